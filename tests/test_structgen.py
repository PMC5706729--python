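"""Synthetic-structure generator: builders, ground truth, determinism."""

import numpy as np
import pytest

from oligotop import (ChainSpec, WT_SPEC, analyze_topology, assign_secondary_structure,
                      build_barrel, build_bilayer, build_chain, build_coil,
                      build_coil_system, build_hairpin, daura_cluster, detect_hbonds,
                      end_to_end, make_ensemble, perturb)
from oligotop.structgen import BETA_PHI_PSI, SIDECHAIN_ZMATRIX, _clashes


class TestChainSpec:
    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            ChainSpec("")
        with pytest.raises(ValueError):
            ChainSpec("AIIGLMZ")
        with pytest.raises(ValueError):
            ChainSpec("AIIGLMV", n_term_cap="FOR")

    def test_supported_alphabet_covers_target_peptides(self):
        for seq in ("AIIGLMV", "AIIVLMV", "AIIGTMV"):
            assert len(ChainSpec(seq)) == 7


class TestBuildChain:
    def test_dihedral_count_checked(self):
        with pytest.raises(ValueError):
            build_chain(WT_SPEC, [BETA_PHI_PSI] * 6)

    def test_backbone_and_caps_present(self, extended_chain):
        c = extended_chain
        for r in range(1, 8):
            for name in ("N", "CA", "C", "O"):
                assert c.atom_index("A", r, name) is not None
        assert c.atom_index("A", 0, "CH3") is not None      # ACE
        assert c.atom_index("A", 8, "N") is not None        # NH2

    def test_standard_bond_lengths(self, extended_chain):
        c = extended_chain
        n = c.xyz[c.atom_index("A", 3, "N")]
        ca = c.xyz[c.atom_index("A", 3, "CA")]
        co = c.xyz[c.atom_index("A", 3, "C")]
        assert np.linalg.norm(ca - n) == pytest.approx(0.1458, abs=1e-6)
        assert np.linalg.norm(co - ca) == pytest.approx(0.1525, abs=1e-6)

    def test_sign_flip_shortens_end_to_end(self, extended_chain):
        dihedrals = [BETA_PHI_PSI] * 7
        dihedrals[3] = (-BETA_PHI_PSI[0], -BETA_PHI_PSI[1])
        kinked = build_chain(WT_SPEC, dihedrals)
        assert end_to_end(kinked, "A") < end_to_end(extended_chain, "A")

    def test_helix_dihedrals_give_helix_assignment(self, helix_chain):
        ss = assign_secondary_structure(helix_chain)
        labels = ss.chain_string(helix_chain, "A")
        assert set(labels[2:-2]) == {"H"}


class TestSheetBuilders:
    def test_bilayer_ground_truth_matches_classifier(self, bilayer42):
        conf, gt = bilayer42
        label = analyze_topology(conf).label
        assert (label.cls, label.layer_sizes) == ("bilayer", (4, 2))
        assert gt.topology == "bilayer" and gt.layer_sizes == (4, 2)

    def test_monolayer_degenerate_bilayer(self, monolayer6):
        conf, gt = monolayer6
        assert gt.topology == "monolayer"
        assert analyze_topology(conf).label.cls == "monolayer"

    def test_flat_construction_has_zero_twist(self, bilayer33):
        conf, _ = bilayer33
        for t in analyze_topology(conf).twists:
            assert t == pytest.approx(0.0, abs=0.5)

    def test_infeasible_spacing_rejected(self):
        with pytest.raises(ValueError):
            build_bilayer(WT_SPEC, m=2, n=0, interstrand_spacing=0.3)
        with pytest.raises(ValueError):
            build_bilayer(WT_SPEC, m=2, n=2, interlayer_spacing=0.2)
        with pytest.raises(ValueError):
            build_bilayer(WT_SPEC, m=2, n=0, twist=55.0)

    @pytest.mark.parametrize("orientation,shift,expected", [
        ("antiparallel", 0, "AP0"), ("parallel", 0, "P0"),
        ("parallel", 1, "P1"), ("parallel", 2, "P2"),
    ])
    def test_register_truth_recorded(self, orientation, shift, expected):
        _, gt = build_bilayer(WT_SPEC, m=2, n=0, orientation=orientation,
                              register_shift=shift)
        assert gt.pairings[0].register_class == expected


class TestBarrel:
    def test_hexamer_barrel_round_trip(self, barrel6):
        conf, gt = barrel6
        assert gt.topology == "barrel"
        assert analyze_topology(conf).label.cls == "barrel"

    def test_minimal_barrel_is_4_cycle(self):
        conf, gt = build_barrel(WT_SPEC, n_strands=4)
        ft = analyze_topology(conf)
        assert ft.label.cls == "barrel"
        assert ft.graph.number_of_edges() == 4

    def test_broken_seam_gives_open_sheet(self):
        conf, gt = build_barrel(WT_SPEC, n_strands=6, broken_seam=True)
        assert gt.topology == "monolayer"
        assert analyze_topology(conf).label.cls == "monolayer"

    def test_preconditions(self):
        with pytest.raises(ValueError):
            build_barrel(WT_SPEC, n_strands=3)
        with pytest.raises(ValueError):
            build_barrel(WT_SPEC, n_strands=6, radius=0.1)
        with pytest.raises(ValueError):
            # offsets that cannot cancel around the ring
            build_barrel(WT_SPEC, n_strands=6, register_offsets=[1, 0, 0, 0, 0, 0])


class TestHairpin:
    def test_intrachain_hbond_formed(self, hairpin):
        intra = [h for h in detect_hbonds(hairpin)
                 if h.same_chain and h.contact_class == "MC-MC"]
        assert len(intra) >= 1

    def test_preconditions(self):
        with pytest.raises(ValueError):
            build_hairpin(WT_SPEC, 1)
        with pytest.raises(ValueError):
            build_hairpin(ChainSpec("AIGL"), 2)


class TestCoil:
    def test_self_avoiding(self):
        coil = build_coil(WT_SPEC, seed=3)
        assert not _clashes(coil)

    def test_system_is_disordered(self, coil_hexamer):
        conf, gt = coil_hexamer
        assert gt.topology == "disordered"
        assert analyze_topology(conf).label.cls == "disordered"


class TestPerturb:
    def test_zero_amplitude_identity(self, barrel6):
        conf, _ = barrel6
        assert np.array_equal(perturb(conf, 0.0, seed=1).xyz, conf.xyz)

    def test_deterministic(self, barrel6):
        conf, _ = barrel6
        a = perturb(conf, 0.02, seed=42)
        b = perturb(conf, 0.02, seed=42)
        assert np.array_equal(a.xyz, b.xyz)

    def test_negative_amplitude_rejected(self, barrel6):
        with pytest.raises(ValueError):
            perturb(barrel6[0], -0.1, seed=0)

    def test_small_noise_keeps_barrel_label(self, barrel6):
        conf, _ = barrel6
        ok = sum(analyze_topology(perturb(conf, 0.02, seed=s)).label.cls == "barrel"
                 for s in range(10))
        assert ok >= 9


class TestMakeEnsemble:
    def test_bookkeeping_and_order(self):
        ens = make_ensemble([
            ("barrel", {"spec": WT_SPEC, "n_strands": 6}, 3, 0.0, 1),
            ("bilayer", {"spec": WT_SPEC, "m": 3, "n": 3}, 2, 0.0, 2),
        ])
        assert len(ens) == 5
        assert [gt.topology for gt in ens.ground_truth] == \
            ["barrel"] * 3 + ["bilayer"] * 2

    def test_bit_identical_given_seeds(self):
        recipe = [("bilayer", {"spec": WT_SPEC, "m": 3, "n": 3}, 3, 0.03, 7)]
        a, b = make_ensemble(recipe), make_ensemble(recipe)
        assert all(np.array_equal(x.xyz, y.xyz) for x, y in zip(a.frames, b.frames))

    def test_empty_recipe_rejected(self):
        with pytest.raises(ValueError):
            make_ensemble([])

    def test_mixture_recovers_clusters(self, mixed_ensemble):
        cr = daura_cluster(mixed_ensemble, cutoff=0.35)
        assert cr.n_clusters >= 3

    def test_all_sidechain_templates_used(self):
        # every supported residue type builds without error and places all
        # of its template atoms
        spec = ChainSpec("AGILMTV")
        conf = build_chain(spec, [BETA_PHI_PSI] * 7)
        for i, aa3 in enumerate(["ALA", "GLY", "ILE", "LEU", "MET", "THR", "VAL"]):
            for name, *_ in SIDECHAIN_ZMATRIX[aa3]:
                assert conf.atom_index("A", i + 1, name) is not None
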