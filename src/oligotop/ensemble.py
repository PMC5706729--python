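"""Ensemble-level statistics: Daura clustering, propensities, contact maps,
SASA, 1D/2D distributions, free-energy landscapes and convergence checks.

Conventions (stated because the literature often leaves them implicit):
contacts use a 0.54 nm heavy-atom cutoff between the designated moiety
groups; the parallel/antiparallel boundary for strand-axis angles is 90°;
PMF bins are integer H-bond counts × 0.01 nm in RG; block error bars are
the standard deviation across block means; SASA uses Bondi radii with a
0.14 nm water probe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .core import Conformation, Ensemble, VDW_RADIUS
from .geometry import ca_rmsd, end_to_end, radius_of_gyration
from .hbonds import detect_hbonds
from .dssp import assign_secondary_structure

KB = 0.0019872          # kcal/(mol·K)
CONTACT_CUTOFF = 0.54   # nm
SASA_PROBE = 0.14       # nm
SASA_POINTS = 960


# ---------------------------------------------------------------------------
# Daura clustering


@dataclass
class ClusterResult:
    """Daura clustering outcome, clusters ordered by descending population."""

    labels: np.ndarray          # per-frame cluster id
    centers: list[int]          # per-cluster center frame index
    populations: np.ndarray     # per-cluster fraction, sums to 1

    @property
    def n_clusters(self) -> int:
        return len(self.centers)

    def members(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.labels == k)


def rmsd_matrix(e: Ensemble, mapping: str = "fixed") -> np.ndarray:
    n = len(e)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = ca_rmsd(e.frames[i], e.frames[j], mapping=mapping)
    return d


def daura_cluster(e: Ensemble, cutoff: float = 0.35, mapping: str = "fixed",
                  precomputed: Optional[np.ndarray] = None) -> ClusterResult:
    """Iterative neighbor-count (Daura) clustering under an RMSD cutoff.

    Repeatedly the frame with the most unassigned neighbors within
    ``cutoff`` (ties: lowest frame index) becomes a cluster center; it and
    its neighbors are removed.  Clusters are renumbered by descending
    population with center frame index breaking population ties.
    """
    if len(e) == 0:
        raise ValueError("need at least one frame")
    d = rmsd_matrix(e, mapping) if precomputed is None else precomputed
    n = len(e)
    neighbor = d <= cutoff
    np.fill_diagonal(neighbor, True)
    unassigned = np.ones(n, dtype=bool)
    labels = np.full(n, -1, dtype=int)
    raw: list[tuple[int, int]] = []   # (center, size)
    while unassigned.any():
        counts = (neighbor & unassigned[None, :]).sum(axis=1)
        counts[~unassigned] = -1
        center = int(np.argmax(counts))          # argmax takes the lowest index on ties
        members = np.flatnonzero(neighbor[center] & unassigned)
        labels[members] = len(raw)
        raw.append((center, len(members)))
        unassigned[members] = False
    order = sorted(range(len(raw)), key=lambda k: (-raw[k][1], raw[k][0]))
    remap = {old: new for new, old in enumerate(order)}
    labels = np.array([remap[x] for x in labels])
    centers = [raw[old][0] for old in order]
    populations = np.array([raw[old][1] for old in order], dtype=float) / n
    return ClusterResult(labels=labels, centers=centers, populations=populations)


# ---------------------------------------------------------------------------
# Secondary-structure propensities


def _frame_ss_fractions(conf: Conformation, fold_bend_turn: bool) -> dict[str, float]:
    return assign_secondary_structure(conf).fractions(fold_bend_turn)


def ss_propensity(e: Ensemble, n_blocks: int = 2, fold_bend_turn_into_coil: bool = False,
                  ss_cache: Optional[list] = None):
    """Per-residue-position and overall secondary-structure propensities.

    Fractions are over frames × (chain, residue) observations pooled by
    residue position along the chain.  Errors are the standard deviation
    of the per-block means over ``n_blocks`` contiguous frame blocks
    (two-block and five-block schemes are the conventional choices).

    Returns (per_residue_df, overall_df); the per-residue frame carries a
    MultiIndex (class, stat in {mean, err}).
    """
    assignments = ss_cache or [assign_secondary_structure(c) for c in e]
    classes = sorted({"helix", "β-sheet", "β-bridge", "bend", "turn", "coil"})
    if fold_bend_turn_into_coil:
        classes = [c for c in classes if c not in ("bend", "turn")]

    chain0 = e.frames[0].chains[0]
    n_res = len(e.frames[0].sequence(chain0))
    blocks = np.array_split(np.arange(len(e)), n_blocks)

    def tally(frame_idx: Sequence[int]) -> tuple[np.ndarray, dict[str, float]]:
        per_res = np.zeros((n_res, len(classes)))
        count = 0
        overall = {c: 0.0 for c in classes}
        n_obs = 0
        for fi in frame_idx:
            conf = e.frames[fi]
            red = assignments[fi].reduced(fold_bend_turn_into_coil)
            for chain in conf.chains:
                keys = [k for k in conf.residue_keys() if k[0] == chain]
                for pos, key in enumerate(keys):
                    cls = red.get(key, "coil")
                    if cls in overall:
                        overall[cls] += 1
                        per_res[pos, classes.index(cls)] += 1
                    n_obs += 1
            count += len(conf.chains)
        per_res /= max(count, 1)
        overall = {c: v / max(n_obs, 1) for c, v in overall.items()}
        return per_res, overall

    per_block = [tally(b) for b in blocks if len(b)]
    full_res, full_all = tally(np.arange(len(e)))
    res_stack = np.stack([p[0] for p in per_block])
    res_err = res_stack.std(axis=0, ddof=0)

    cols = pd.MultiIndex.from_product([classes, ["mean", "err"]])
    per_residue = pd.DataFrame(index=pd.RangeIndex(1, n_res + 1, name="residue"),
                               columns=cols, dtype=float)
    for ci, c in enumerate(classes):
        per_residue[(c, "mean")] = full_res[:, ci]
        per_residue[(c, "err")] = res_err[:, ci]

    overall = pd.DataFrame({
        "mean": [full_all[c] for c in classes],
        "err": [np.std([p[1][c] for p in per_block], ddof=0) for c in classes],
    }, index=pd.Index(classes, name="class"))
    return per_residue, overall


def propensity_by_cluster(e: Ensemble, clusters: ClusterResult,
                          fold_bend_turn_into_coil: bool = False,
                          ss_cache: Optional[list] = None) -> pd.DataFrame:
    """Mean per-frame secondary-structure class fractions for each cluster."""
    assignments = ss_cache or [assign_secondary_structure(c) for c in e]
    fracs = [assignments[i].fractions(fold_bend_turn_into_coil) for i in range(len(e))]
    classes = sorted(fracs[0])
    rows = []
    for k in range(clusters.n_clusters):
        members = clusters.members(k)
        if members.size == 0:
            raise ValueError(f"cluster {k} has no members")
        rows.append({c: float(np.mean([fracs[i][c] for i in members])) for c in classes})
    return pd.DataFrame(rows, index=pd.RangeIndex(clusters.n_clusters, name="cluster"))


# ---------------------------------------------------------------------------
# Contact maps


@dataclass
class ContactMap:
    """Interchain residue–residue contact probabilities (symmetric)."""

    mc_mc: np.ndarray
    sc_sc: np.ndarray
    residue_labels: list[str]
    cutoff: float


def _moiety_groups(conf: Conformation):
    """Heavy-atom indices per (chain, residue position), split MC/SC."""
    groups: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
    for chain in conf.chains:
        keys = [k for k in conf.residue_keys() if k[0] == chain]
        per_res = []
        for (c, r) in keys:
            mask = (conf.chain_ids == c) & (conf.res_ids == r) & conf.is_heavy
            mc = np.flatnonzero(mask & conf.is_backbone)
            sc = np.flatnonzero(mask & ~conf.is_backbone)
            per_res.append((mc, sc))
        groups[chain] = per_res
    return groups


def contact_maps(e: Ensemble, cutoff: float = CONTACT_CUTOFF) -> ContactMap:
    """Interpeptide MC-MC and SC-SC contact probability maps.

    Residues i and j (of distinct chains) are in contact when the minimal
    distance between the designated heavy-atom groups is below ``cutoff``;
    probabilities average over frames × unordered chain pairs, symmetrized
    over the two chain-to-axis assignments.
    """
    conf0 = e.frames[0]
    n_res = len(conf0.sequence(conf0.chains[0]))
    acc_mc = np.zeros((n_res, n_res))
    acc_sc = np.zeros((n_res, n_res))
    n_obs = 0
    for conf in e:
        groups = _moiety_groups(conf)
        chains = conf.chains
        for a in range(len(chains)):
            for b in range(a + 1, len(chains)):
                ga, gb = groups[chains[a]], groups[chains[b]]
                for which, acc in ((0, acc_mc), (1, acc_sc)):
                    hit = np.zeros((n_res, n_res), dtype=bool)
                    for i in range(n_res):
                        ia = ga[i][which]
                        if ia.size == 0:
                            continue
                        xa = conf.xyz[ia]
                        for j in range(n_res):
                            jb = gb[j][which]
                            if jb.size == 0:
                                continue
                            d2 = ((xa[:, None, :] - conf.xyz[jb][None, :, :]) ** 2).sum(-1)
                            if d2.min() < cutoff ** 2:
                                hit[i, j] = True
                    acc += (hit | hit.T)
                n_obs += 1
    seq = conf0.sequence(conf0.chains[0])
    labels = [residue_label(seq, i + 1) for i in range(n_res)]
    return ContactMap(acc_mc / max(n_obs, 1), acc_sc / max(n_obs, 1), labels, cutoff)


def residue_label(seq: str, pos: int) -> str:
    """Human-readable residue label; the Aβ30–36 family keeps the parent
    peptide's 30…36 numbering."""
    offset = 29 if len(seq) == 7 and seq[0] == "A" and seq[-1] == "V" else 0
    return f"{seq[pos - 1]}{pos + offset}"


# ---------------------------------------------------------------------------
# SASA (Shrake–Rupley)


@dataclass
class SASAProfile:
    """Solvent-accessible surface areas (nm²)."""

    per_atom: np.ndarray
    per_residue: pd.Series          # indexed by (chain, res_id)
    total: float
    normalized: Optional[float] = None   # total / sum of isolated-chain totals


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = math.pi * (1.0 + math.sqrt(5.0)) * k
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def sasa(conf: Conformation, probe: float = SASA_PROBE,
         n_sphere_points: int = SASA_POINTS, normalize: bool = False) -> SASAProfile:
    """Shrake–Rupley SASA with Bondi radii and a water-sized probe.

    Each atom is sampled on ``n_sphere_points`` quasi-uniform sphere points
    at radius r_vdw + probe; a point is accessible when outside every
    neighbor's probe-expanded sphere.  ``normalize=True`` additionally
    divides the total by the sum of each chain's SASA computed in
    isolation.
    """
    try:
        radii = np.array([VDW_RADIUS[el] for el in conf.elements]) + probe
    except KeyError as exc:
        raise ValueError(f"unknown element {exc.args[0]!r}") from exc
    pts = _sphere_points(n_sphere_points)
    xyz = conf.xyz
    n = conf.n_atoms
    from scipy.spatial import cKDTree

    tree = cKDTree(xyz)
    per_atom = np.zeros(n)
    rmax = radii.max()
    for i in range(n):
        shell = xyz[i] + radii[i] * pts
        neigh = [j for j in tree.query_ball_point(xyz[i], radii[i] + rmax) if j != i]
        accessible = np.ones(n_sphere_points, dtype=bool)
        for j in neigh:
            d2 = ((shell - xyz[j]) ** 2).sum(axis=1)
            accessible &= d2 > radii[j] ** 2
            if not accessible.any():
                break
        per_atom[i] = accessible.mean() * 4.0 * math.pi * radii[i] ** 2

    idx = pd.MultiIndex.from_arrays([conf.chain_ids, conf.res_ids],
                                    names=("chain", "res_id"))
    per_res = pd.Series(per_atom, index=idx).groupby(level=(0, 1), sort=False).sum()
    total = float(per_atom.sum())
    normalized = None
    if normalize:
        iso = 0.0
        for chain in conf.chains:
            mask = conf.chain_mask(chain)
            sub = Conformation(conf.names[mask], conf.elements[mask],
                               conf.res_ids[mask], conf.res_names[mask],
                               conf.chain_ids[mask], conf.xyz[mask])
            iso += sasa(sub, probe, n_sphere_points).total
        normalized = total / iso
    return SASAProfile(per_atom, per_res, total, normalized)


# ---------------------------------------------------------------------------
# Distributions and free-energy landscapes


def pdf1d(values: Sequence[float], bin_width: float,
          range_: Optional[tuple[float, float]] = None) -> tuple[np.ndarray, np.ndarray]:
    """Histogram density (integrates to 1).  Returns (density, bin_edges)."""
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("need at least one value")
    lo, hi = range_ if range_ is not None else (values.min(), values.max())
    n_bins = max(1, int(math.ceil((hi - lo) / bin_width - 1e-9)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    density, edges = np.histogram(values, bins=edges, density=True)
    return density, edges


@dataclass
class PMFGrid:
    """2D free-energy landscape over (interchain H-bond count, RG)."""

    free_energy: np.ndarray     # kcal/mol, NaN where unsampled
    hbond_edges: np.ndarray
    rg_edges: np.ndarray
    temperature: float

    @property
    def occupied(self) -> np.ndarray:
        return ~np.isnan(self.free_energy)


def pmf_from_observables(x: Sequence[float], y: Sequence[float], T: float,
                         x_edges: np.ndarray, y_edges: np.ndarray) -> PMFGrid:
    """F(bin) = −k_B·T·ln(P/P_max); empty bins are NaN, the minimum is 0."""
    counts, xe, ye = np.histogram2d(np.asarray(x, float), np.asarray(y, float),
                                    bins=[x_edges, y_edges])
    with np.errstate(divide="ignore"):
        f = -KB * T * np.log(counts / counts.max())
    f[counts == counts.max()] = 0.0   # exact zero at the global minimum
    f[counts == 0] = np.nan
    return PMFGrid(f, xe, ye, T)


def interchain_hbond_count(conf: Conformation, mc_mc_only: bool = False) -> int:
    hbs = [hb for hb in detect_hbonds(conf) if not hb.same_chain]
    if mc_mc_only:
        hbs = [hb for hb in hbs if hb.contact_class == "MC-MC"]
    return len(hbs)


def pmf2d(e: Ensemble, T: Optional[float] = None, rg_bin: float = 0.01,
          mc_mc_only: bool = False, heavy_only: bool = True) -> PMFGrid:
    """Free-energy landscape over interchain H-bond number × radius of
    gyration, the conventional plane for small-oligomer ensembles."""
    if len(e) == 0:
        raise ValueError("need at least one frame")
    T = e.temperature if T is None else T
    hb = np.array([interchain_hbond_count(c, mc_mc_only) for c in e], dtype=float)
    rg = np.array([radius_of_gyration(c, c.is_heavy if heavy_only else None) for c in e])
    hb_edges = np.arange(hb.min() - 0.5, hb.max() + 1.5)
    lo = math.floor(rg.min() / rg_bin) * rg_bin
    hi = math.ceil(rg.max() / rg_bin) * rg_bin
    rg_edges = np.arange(lo, hi + rg_bin / 2, rg_bin)
    if len(rg_edges) < 2:
        rg_edges = np.array([lo - rg_bin / 2, lo + rg_bin / 2])
    return pmf_from_observables(hb, rg, T, hb_edges, rg_edges)


# ---------------------------------------------------------------------------
# Sheet-angle statistics


def sheet_angle_stats(e: Ensemble, boundary: float = 90.0, bin_width: float = 5.0):
    """Pooled neighboring-strand angle PDF plus parallel/antiparallel split.

    Angles below ``boundary`` count as parallel, at or above as
    antiparallel; the two fractions sum to 1 whenever any angle exists.
    """
    from .topology import analyze_topology, sheet_angle

    angles: list[float] = []
    for conf in e:
        ft = analyze_topology(conf)
        for u, v in ft.graph.edges:
            angles.append(sheet_angle(ft.graph.nodes[u]["strand"],
                                      ft.graph.nodes[v]["strand"]))
    angles_arr = np.asarray(angles)
    if angles_arr.size:
        parallel = float((angles_arr < boundary).mean())
        density, edges = pdf1d(angles_arr, bin_width, range_=(0.0, 180.0))
    else:
        parallel, density, edges = float("nan"), np.array([]), np.array([])
    return {
        "angles": angles_arr,
        "pdf": (density, edges),
        "parallel_fraction": parallel,
        "antiparallel_fraction": 1.0 - parallel if angles_arr.size else float("nan"),
    }


# ---------------------------------------------------------------------------
# Convergence diagnostics


def overlap_coefficient(p: np.ndarray, q: np.ndarray) -> float:
    """∑ min(p, q) for two discrete distributions on the same bins."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    if p.sum() > 0:
        p = p / p.sum()
    if q.sum() > 0:
        q = q / q.sum()
    return float(np.minimum(p, q).sum())


def _hist_pair(a: np.ndarray, b: np.ndarray, bin_width: float):
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    n_bins = max(1, int(math.ceil((hi - lo) / bin_width - 1e-9)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    pa, _ = np.histogram(a, bins=edges)
    pb, _ = np.histogram(b, bins=edges)
    return pa.astype(float), pb.astype(float), edges


#: observable name -> (per-frame extractor giving a list of scalars, bin width)
_CONV_OBSERVABLES: dict[str, tuple[Callable, float]] = {
    "end_to_end": (lambda c: [end_to_end(c, ch) for ch in c.chains], 0.05),
    "hbond_count": (lambda c: [float(len(detect_hbonds(c)))], 1.0),
    "rg": (lambda c: [radius_of_gyration(c, c.is_heavy)], 0.01),
    "sasa": (lambda c: [sasa(c).total], 0.25),
}


def convergence_check(eA: Ensemble, eB: Ensemble) -> dict[str, dict]:
    """Two-window convergence diagnostic.

    For end-to-end distance, H-bond count, RG, SASA and secondary-structure
    fractions the report holds both distributions and their overlap
    coefficient (∑ min over shared bins); identical ensembles give 1.0,
    disjoint ones 0.0.
    """
    if len(eA) == 0 or len(eB) == 0:
        raise ValueError("both ensembles need frames")
    seqA = sorted(eA.frames[0].sequence(c) for c in eA.frames[0].chains)
    seqB = sorted(eB.frames[0].sequence(c) for c in eB.frames[0].chains)
    if seqA != seqB:
        raise ValueError("incompatible systems")
    report: dict[str, dict] = {}
    for name, (extract, width) in _CONV_OBSERVABLES.items():
        va = np.array([x for c in eA for x in extract(c)], dtype=float)
        vb = np.array([x for c in eB for x in extract(c)], dtype=float)
        pa, pb, edges = _hist_pair(va, vb, width)
        report[name] = {"overlap": overlap_coefficient(pa, pb),
                        "pdf_a": pa, "pdf_b": pb, "edges": edges}
    fa = ss_propensity(eA)[1]["mean"]
    fb = ss_propensity(eB)[1]["mean"]
    report["ss_fractions"] = {
        "overlap": overlap_coefficient(fa.to_numpy(), fb.to_numpy()),
        "pdf_a": fa, "pdf_b": fb, "edges": list(fa.index),
    }
    return report
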