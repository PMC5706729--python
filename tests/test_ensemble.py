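"""Ensemble statistics: clustering, propensities, contacts, SASA, PMF, PDFs."""

import math

import numpy as np
import pytest

from oligotop import (Conformation, Ensemble, WT_SPEC, build_bilayer, build_chain,
                      contact_maps, convergence_check, daura_cluster, make_ensemble,
                      overlap_coefficient, pdf1d, perturb, pmf2d,
                      pmf_from_observables, propensity_by_cluster, sasa,
                      sheet_angle_stats, ss_propensity)
from oligotop.ensemble import KB, rmsd_matrix
from oligotop.structgen import BETA_PHI_PSI


def brute_force_daura(dist, cutoff):
    """Literal re-implementation used as an independent oracle: recompute
    neighbor counts from scratch each round."""
    n = len(dist)
    unassigned = set(range(n))
    labels = [-1] * n
    clusters = []
    while unassigned:
        best_center, best_members = None, None
        for c in sorted(unassigned):
            members = {j for j in unassigned if dist[c][j] <= cutoff} | {c}
            if best_members is None or len(members) > len(best_members):
                best_center, best_members = c, members
        clusters.append((best_center, len(best_members)))
        for m in best_members:
            labels[m] = len(clusters) - 1
        unassigned -= best_members
    order = sorted(range(len(clusters)), key=lambda k: (-clusters[k][1], clusters[k][0]))
    remap = {old: new for new, old in enumerate(order)}
    return [remap[x] for x in labels]


class TestDaura:
    def test_identical_frames_one_cluster(self, barrel6):
        conf, _ = barrel6
        ens = Ensemble([conf.copy() for _ in range(5)])
        cr = daura_cluster(ens)
        assert cr.n_clusters == 1
        assert cr.populations[0] == 1.0

    def test_distant_frames_singletons(self, barrel6):
        conf, _ = barrel6
        frames = []
        for k in range(4):
            shifted = conf.with_xyz(conf.xyz + np.array([5.0 * k, 0, 0]))
            frames.append(perturb(shifted, 0.3, seed=k))
        cr = daura_cluster(Ensemble(frames), cutoff=0.05)
        assert cr.n_clusters == 4

    @pytest.mark.parametrize("seed", range(5))
    def test_membership_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        base, _ = build_bilayer(WT_SPEC, m=2, n=0)
        frames = [perturb(base, float(rng.uniform(0.05, 0.4)), seed=seed * 100 + j)
                  for j in range(24)]
        ens = Ensemble(frames)
        d = rmsd_matrix(ens)
        cutoff = float(np.median(d))
        ours = daura_cluster(ens, cutoff=cutoff, precomputed=d)
        oracle = brute_force_daura(d.tolist(), cutoff)
        assert ours.labels.tolist() == oracle

    def test_populations_sum_and_ordering(self, mixed_ensemble):
        cr = daura_cluster(mixed_ensemble)
        assert cr.populations.sum() == pytest.approx(1.0)
        assert all(cr.populations[i] >= cr.populations[i + 1]
                   for i in range(cr.n_clusters - 1))
        for k in range(cr.n_clusters):
            assert cr.labels[cr.centers[k]] == k


class TestPropensities:
    def test_pure_sheet_ensemble(self, bilayer33):
        conf, _ = bilayer33
        ens = Ensemble([conf.copy() for _ in range(4)])
        per_res, overall = ss_propensity(ens)
        assert overall.loc["β-sheet", "mean"] > 0.8
        # interior residues fully sheet
        assert per_res[("β-sheet", "mean")].iloc[2] == pytest.approx(1.0, abs=0.05)
        # identical blocks give zero error
        assert overall["err"].max() == pytest.approx(0.0, abs=1e-12)

    def test_mixture_is_average_of_components(self, bilayer33, coil_hexamer):
        sheet, _ = bilayer33
        coil, _ = coil_hexamer
        ens = Ensemble([sheet.copy(), coil.copy()] * 2)
        _, overall = ss_propensity(ens)
        _, sheet_only = ss_propensity(Ensemble([sheet]))
        _, coil_only = ss_propensity(Ensemble([coil]))
        expected = (sheet_only["mean"] + coil_only["mean"]) / 2
        assert np.allclose(overall["mean"], expected, atol=1e-9)

    def test_by_cluster_equals_subset_recomputation(self, mixed_ensemble):
        cr = daura_cluster(mixed_ensemble)
        table = propensity_by_cluster(mixed_ensemble, cr)
        k = 0
        members = cr.members(k)
        sub = Ensemble([mixed_ensemble.frames[i] for i in members])
        _, overall = ss_propensity(sub, n_blocks=1)
        assert table.loc[k, "β-sheet"] == pytest.approx(
            overall.loc["β-sheet", "mean"], abs=1e-9)


class TestContacts:
    def test_far_chains_zero_map(self):
        a = build_chain(WT_SPEC, [BETA_PHI_PSI] * 7, chain_id="A")
        b = build_chain(WT_SPEC, [BETA_PHI_PSI] * 7, chain_id="B")
        b = b.with_xyz(b.xyz + np.array([0.0, 10.0, 0.0]))
        from oligotop.core import concat_chains

        conf = concat_chains([a, b])
        cm = contact_maps(Ensemble([conf]))
        assert cm.mc_mc.max() == 0.0 and cm.sc_sc.max() == 0.0

    def test_symmetry_and_range(self, mixed_ensemble):
        cm = contact_maps(mixed_ensemble[:4])
        for m in (cm.mc_mc, cm.sc_sc):
            assert np.array_equal(m, m.T)
            assert m.min() >= 0.0 and m.max() <= 1.0

    def test_packed_sidechains_certain_contact(self, ap_pair):
        conf, _ = ap_pair
        cm = contact_maps(Ensemble([conf]))
        assert cm.mc_mc.max() == 1.0  # H-bonded backbones are in contact

    def test_chain_relabeling_invariance(self, bilayer33):
        conf, _ = bilayer33
        relabeled = conf.copy()
        mapping = {"A": "F", "B": "E", "C": "D", "D": "C", "E": "B", "F": "A"}
        relabeled.chain_ids = np.array([mapping[c] for c in conf.chain_ids],
                                       dtype=object)
        cm1 = contact_maps(Ensemble([conf]))
        cm2 = contact_maps(Ensemble([relabeled]))
        assert np.allclose(cm1.sc_sc, cm2.sc_sc)


class TestSASA:
    def test_isolated_atom_analytic(self):
        conf = Conformation(["O"], ["O"], [1], ["HOH"], ["A"], [[0.0, 0.0, 0.0]])
        prof = sasa(conf, n_sphere_points=960)
        r = 0.152 + 0.14
        assert prof.total == pytest.approx(4 * math.pi * r ** 2, rel=0.01)

    def test_buried_atom_fully_occluded(self):
        # central atom caged by 14 overlapping neighbors
        shells = [[0.0, 0.0, 0.0]]
        for dx in (-1, 1):
            for axis in range(3):
                v = [0.0, 0.0, 0.0]
                v[axis] = 0.18 * dx
                shells.append(v)
        for sx in (-1, 1):
            for sy in (-1, 1):
                for sz in (-1, 1):
                    shells.append([0.13 * sx, 0.13 * sy, 0.13 * sz])
        n = len(shells)
        conf = Conformation(["C"] * n, ["C"] * n, list(range(1, n + 1)),
                            ["UNK"] * n, ["A"] * n, shells)
        prof = sasa(conf)
        assert prof.per_atom[0] == pytest.approx(0.0, abs=1e-9)

    def test_quadrature_agreement_with_dense_oracle(self, ap_pair):
        conf, _ = ap_pair
        coarse = sasa(conf, n_sphere_points=960).per_residue
        dense = sasa(conf, n_sphere_points=10000).per_residue
        rel = (coarse - dense).abs() / dense.clip(lower=1e-9)
        assert rel.max() < 0.02

    def test_normalized_fraction_in_unit_interval(self, bilayer33):
        conf, _ = bilayer33
        prof = sasa(conf, normalize=True)
        assert 0.0 < prof.normalized <= 1.0


class TestPMF:
    def test_single_bin_is_zero(self):
        grid = pmf_from_observables([3.0] * 10, [1.0] * 10, 310.0,
                                    np.array([2.5, 3.5]), np.array([0.95, 1.05]))
        assert np.nanmin(grid.free_energy) == 0.0
        assert grid.occupied.sum() == 1

    def test_two_bin_closed_form(self):
        n = 1000
        x = [0.0] * n + [1.0] * int(n / math.e)
        grid = pmf_from_observables(x, [0.0] * len(x), 310.0,
                                    np.array([-0.5, 0.5, 1.5]), np.array([-1.0, 1.0]))
        delta = grid.free_energy[1, 0] - grid.free_energy[0, 0]
        assert delta == pytest.approx(KB * 310.0, rel=0.01)

    def test_two_population_delta_f_within_3_se(self, rng):
        w1, w2, n = 0.7, 0.3, 10_000
        draws = rng.random(n) < w2
        x = draws.astype(float)
        grid = pmf_from_observables(x, np.zeros(n), 310.0,
                                    np.array([-0.5, 0.5, 1.5]), np.array([-1.0, 1.0]))
        delta = grid.free_energy[1, 0] - grid.free_energy[0, 0]
        expected = -KB * 310.0 * math.log(w2 / w1)
        n1, n2 = (~draws).sum(), draws.sum()
        se = KB * 310.0 * math.sqrt(1.0 / n1 + 1.0 / n2)
        assert abs(delta - expected) <= 3 * se

    def test_pipeline_pmf_minimum_exactly_zero(self, mixed_ensemble):
        grid = pmf2d(mixed_ensemble[:6])
        assert np.nanmin(grid.free_energy) == 0.0
        assert np.isnan(grid.free_energy[~grid.occupied]).all()


class TestPdf1d:
    def test_constant_values_single_bin(self):
        density, edges = pdf1d([2.0, 2.0, 2.0], 0.5)
        assert len(density) == 1
        assert density[0] == pytest.approx(1 / 0.5)

    def test_normalization(self, rng):
        density, edges = pdf1d(rng.normal(size=2000), 0.1)
        assert (density * np.diff(edges)).sum() == pytest.approx(1.0, abs=1e-9)

    def test_uniform_samples_flat(self, rng):
        density, edges = pdf1d(rng.random(100_000), 0.1, range_=(0.0, 1.0))
        assert np.allclose(density, 1.0, atol=0.05)

    def test_bad_bin_width(self):
        with pytest.raises(ValueError):
            pdf1d([1.0], 0.0)


class TestSheetAngles:
    def test_all_parallel_ensemble(self):
        conf, _ = build_bilayer(WT_SPEC, m=3, n=0, orientation="parallel")
        stats = sheet_angle_stats(Ensemble([conf]))
        assert stats["parallel_fraction"] == 1.0
        assert stats["antiparallel_fraction"] == 0.0

    def test_mixed_fractions_exact_at_zero_noise(self):
        par, _ = build_bilayer(WT_SPEC, m=4, n=0, orientation="parallel")
        anti, _ = build_bilayer(WT_SPEC, m=3, n=0, orientation="antiparallel")
        stats = sheet_angle_stats(Ensemble([par, anti]))
        # 3 parallel edges + 2 antiparallel edges
        assert stats["parallel_fraction"] == pytest.approx(0.6)
        assert stats["antiparallel_fraction"] == pytest.approx(0.4)

    def test_fractions_sum_to_one(self, mixed_ensemble):
        stats = sheet_angle_stats(mixed_ensemble[:5])
        assert stats["parallel_fraction"] + stats["antiparallel_fraction"] == \
            pytest.approx(1.0)


class TestConvergence:
    def test_identical_ensembles_full_overlap(self, mixed_ensemble):
        half = mixed_ensemble[:4]
        rep = convergence_check(half, half)
        for name, info in rep.items():
            assert info["overlap"] == pytest.approx(1.0, abs=1e-9), name

    def test_disjoint_supports_zero_overlap(self):
        assert overlap_coefficient([1, 0, 0], [0, 0, 1]) == 0.0

    def test_same_distribution_samples_overlap_high(self, rng):
        a = rng.normal(size=1000)
        b = rng.normal(size=1000)
        width = 0.25
        edges = np.arange(-4, 4, width)
        pa, _ = np.histogram(a, bins=edges)
        pb, _ = np.histogram(b, bins=edges)
        assert overlap_coefficient(pa, pb) > 0.9

    def test_incompatible_systems_rejected(self, mixed_ensemble, coil_hexamer):
        from oligotop import ChainSpec, build_bilayer

        other, _ = build_bilayer(ChainSpec("AIIVLMV"), m=3, n=3)
        with pytest.raises(ValueError):
            convergence_check(mixed_ensemble[:2], Ensemble([other]))
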