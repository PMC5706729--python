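"""Strand extraction, pairing graph, register, sheet/twist angles, taxonomy."""

import numpy as np
import pytest

from oligotop import (Strand, WT_SPEC, analyze_topology, assign_secondary_structure,
                      build_bilayer, build_coil_system, classify_register,
                      classify_topology, detect_hbonds, extract_strands,
                      pair_strands, perturb, sheet_angle, twist_angle)


def make_strand(chain, start, end, axis):
    axis = np.asarray(axis, float)
    return Strand(chain, start, end, axis / np.linalg.norm(axis), np.zeros(3))


class TestExtractStrands:
    def test_all_coil_gives_empty_list(self, coil_hexamer):
        conf, _ = coil_hexamer
        ss = assign_secondary_structure(conf)
        assert extract_strands(ss, conf) == []

    def test_barrel_gives_one_strand_per_chain(self, barrel6):
        conf, _ = barrel6
        strands = extract_strands(assign_secondary_structure(conf), conf)
        assert sorted(s.chain for s in strands) == list("ABCDEF")

    def test_min_length_threshold(self, ap_pair):
        conf, _ = ap_pair
        ss = assign_secondary_structure(conf)
        long_enough = extract_strands(ss, conf, min_length=3)
        too_strict = extract_strands(ss, conf, min_length=8)
        assert len(long_enough) == 2 and too_strict == []


class TestPairStrands:
    def test_single_hbond_is_not_an_edge(self, ap_pair):
        conf, _ = ap_pair
        ss = assign_secondary_structure(conf)
        strands = extract_strands(ss, conf)
        bonds = [h for h in detect_hbonds(conf)
                 if not h.same_chain and h.contact_class == "MC-MC"]
        g_all = pair_strands(strands, bonds, conf)
        g_one = pair_strands(strands, bonds[:1], conf)
        assert g_all.number_of_edges() == 1
        assert g_one.number_of_edges() == 0

    @pytest.mark.parametrize("orientation,shift,cls", [
        ("antiparallel", 0, "AP0"), ("parallel", 0, "P0"),
        ("parallel", 1, "P1"), ("parallel", 2, "P2"),
        ("antiparallel", 1, "other"),
    ])
    def test_register_round_trip(self, orientation, shift, cls):
        conf, _ = build_bilayer(WT_SPEC, m=2, n=0, orientation=orientation,
                                register_shift=shift)
        ft = analyze_topology(conf)
        assert ft.edge_classes == [cls]
        (u, v) = next(iter(ft.graph.edges))
        assert abs(ft.graph.edges[u, v]["register_shift"]) == shift


class TestClassifyRegister:
    @pytest.mark.parametrize("orientation,shift,expected", [
        ("antiparallel", 0, "AP0"), ("parallel", 0, "P0"), ("parallel", 1, "P1"),
        ("parallel", 2, "P2"), ("antiparallel", 2, "other"),
        ("parallel", 3, "other"), ("parallel", -1, "P1"),
    ])
    def test_named_classes(self, orientation, shift, expected):
        edge = {"orientation": orientation, "register_shift": shift}
        assert classify_register(edge) == expected


class TestAngles:
    def test_sheet_angle_parallel_antiparallel_self(self):
        a = make_strand("A", 1, 7, [1, 0, 0])
        b = make_strand("B", 1, 7, [1, 0.001, 0])
        c = make_strand("C", 1, 7, [-1, 0.001, 0])
        assert sheet_angle(a, b) == pytest.approx(0.0, abs=0.1)
        assert sheet_angle(a, c) == pytest.approx(180.0, abs=0.1)
        assert sheet_angle(a, a) == 0.0

    def test_flat_parallel_sheet_twist_zero(self):
        conf, _ = build_bilayer(WT_SPEC, m=3, n=0, orientation="parallel")
        ft = analyze_topology(conf)
        assert ft.twists[0] == pytest.approx(0.0, abs=0.5)

    def test_supplementary_angle_rule_on_flat_antiparallel_sheet(self):
        """Antiparallel neighbors have ~180° axis angles; the twist must be
        reported as the supplement, ~0°, never ~180°."""
        conf, _ = build_bilayer(WT_SPEC, m=3, n=0, orientation="antiparallel")
        ft = analyze_topology(conf)
        assert ft.twists[0] == pytest.approx(0.0, abs=0.5)

    @pytest.mark.parametrize("imposed", [0.0, 10.0, 20.0, 30.0])
    def test_imposed_twist_recovered(self, imposed):
        conf, gt = build_bilayer(WT_SPEC, m=3, n=0, twist=imposed)
        ft = analyze_topology(conf)
        assert gt.twist == imposed
        assert np.mean(ft.twists) == pytest.approx(imposed, abs=2.0)

    def test_twist_always_within_0_90(self, mixed_ensemble):
        for conf in mixed_ensemble:
            for t in analyze_topology(conf).twists:
                assert 0.0 <= t <= 90.0

    def test_single_strand_twist_undefined(self, extended_chain):
        ft = analyze_topology(extended_chain)
        with pytest.raises(ValueError):
            twist_angle(ft.graph)


class TestClassifyTopology:
    def test_taxonomy_round_trips(self, barrel6, bilayer42, bilayer33,
                                  monolayer6, coil_hexamer):
        for (conf, gt) in (barrel6, bilayer42, bilayer33, monolayer6, coil_hexamer):
            label = analyze_topology(conf).label
            assert label.cls == gt.topology
            if gt.layer_sizes:
                assert tuple(label.layer_sizes) == tuple(gt.layer_sizes)

    def test_layer_sizes_canonical_order(self, bilayer42):
        conf, _ = bilayer42
        m, n = analyze_topology(conf).label.layer_sizes
        assert m >= n

    def test_dissociated_sheets_not_a_bilayer(self, bilayer33):
        conf, _ = bilayer33
        xyz = conf.xyz.copy()
        upper = np.isin(conf.chain_ids, list("DEF"))
        xyz[upper, 2] += 5.0  # drift the second sheet far away
        ft = analyze_topology(conf.with_xyz(xyz))
        assert ft.label.cls == "disordered"

    def test_barrel_noise_robustness(self, barrel6):
        conf, _ = barrel6
        ok = sum(analyze_topology(perturb(conf, 0.02, seed=s)).label.cls == "barrel"
                 for s in range(20))
        assert ok >= 19

    def test_renumbering_flip_keeps_named_class(self, ap_pair):
        """Reversing a strand's residue direction flips the orientation label
        but the named register class is unchanged (AP0 stays AP0)."""
        conf, _ = ap_pair
        ft = analyze_topology(conf)
        (u, v) = next(iter(ft.graph.edges))
        edge = ft.graph.edges[u, v]
        flipped = {"orientation": edge["orientation"],
                   "register_shift": -edge["register_shift"]}
        assert classify_register(edge) == classify_register(flipped)
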