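"""Rigid-body superposition, RMSD and scalar geometric observables.

Internal units are nm throughout.  RMSD is computed over Cα atoms after an
optimal (proper-rotation) Kabsch superposition; the radius of gyration is
mass-weighted, RMSD is unweighted — conventions stated here because common
MD tools differ silently.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np

from .core import Conformation


@dataclass(frozen=True)
class Superposition:
    """Result of a Kabsch superposition of P onto Q: x -> rotation @ x + translation."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float


def kabsch_superpose(P: np.ndarray, Q: np.ndarray) -> Superposition:
    """Least-RMSD proper rigid superposition of point set P onto Q.

    Uses the SVD form of the Kabsch algorithm with the determinant sign
    correction, so the returned rotation is always a proper rotation
    (det = +1) even for near-reflective inputs.

    Raises
    ------
    ValueError
        if the point sets differ in size, have fewer than 3 points, or are
        degenerate (all collinear).
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise ValueError(f"point sets differ in shape: {P.shape} vs {Q.shape}")
    if P.ndim != 2 or P.shape[1] != 3 or P.shape[0] < 3:
        raise ValueError("need >= 3 points of dimension 3")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    # Degenerate if the two smallest singular values vanish (collinear set).
    scale = max(S[0], 1e-300)
    if S[1] / scale < 1e-9:
        raise ValueError("degenerate (collinear) point set")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    diff = (P0 @ R.T) - Q0
    rmsd = float(np.sqrt((diff ** 2).sum() / len(P)))
    t = qc - R @ pc
    return Superposition(rotation=R, translation=t, rmsd=rmsd)


def rmsd_after_superposition(P: np.ndarray, Q: np.ndarray) -> float:
    return kabsch_superpose(P, Q).rmsd


def _chain_ca_blocks(conf: Conformation) -> dict[str, np.ndarray]:
    return {c: conf.xyz[conf.ca_indices(c)] for c in conf.chains}


def ca_rmsd(a: Conformation, b: Conformation, mapping: str = "fixed") -> float:
    """Cα-RMSD between two conformations after optimal superposition (nm).

    ``mapping='fixed'`` pairs chains in file order (standard trajectory
    clustering practice).  ``mapping='best-permutation'`` additionally
    minimises over relabelings of identical-sequence chains, useful when the
    oligomer chains are chemically indistinguishable.
    """
    blocks_a, blocks_b = _chain_ca_blocks(a), _chain_ca_blocks(b)
    chains_a, chains_b = list(blocks_a), list(blocks_b)
    if len(chains_a) != len(chains_b):
        raise ValueError("chain composition mismatch")
    seqs_a = [a.sequence(c) for c in chains_a]
    seqs_b = [b.sequence(c) for c in chains_b]
    if sorted(seqs_a) != sorted(seqs_b):
        raise ValueError("chain composition mismatch")

    def stacked(blocks, order):
        return np.concatenate([blocks[c] for c in order], axis=0)

    ref = stacked(blocks_a, chains_a)
    if mapping == "fixed":
        if seqs_a != seqs_b:
            raise ValueError("chain composition mismatch in fixed order")
        return rmsd_after_superposition(ref, stacked(blocks_b, chains_b))
    if mapping != "best-permutation":
        raise ValueError(f"unknown mapping mode {mapping!r}")
    best = np.inf
    for perm in permutations(range(len(chains_b))):
        order = [chains_b[i] for i in perm]
        if [seqs_b[i] for i in perm] != seqs_a:
            continue
        best = min(best, rmsd_after_superposition(ref, stacked(blocks_b, order)))
    if not np.isfinite(best):
        raise ValueError("no sequence-compatible chain mapping")
    return float(best)


def radius_of_gyration(conf: Conformation, selection: np.ndarray | None = None) -> float:
    """Mass-weighted radius of gyration (nm) of an atom selection."""
    idx = np.arange(conf.n_atoms) if selection is None else np.asarray(selection)
    if idx.dtype == bool:
        idx = np.flatnonzero(idx)
    if idx.size == 0:
        raise ValueError("empty selection")
    m = conf.masses[idx]
    x = conf.xyz[idx]
    com = (m[:, None] * x).sum(axis=0) / m.sum()
    return float(np.sqrt((m * ((x - com) ** 2).sum(axis=1)).sum() / m.sum()))


def end_to_end(conf: Conformation, chain: str) -> float:
    """Cα(first residue)–Cα(last residue) distance of one chain (nm), caps excluded."""
    idx = conf.ca_indices(chain)
    if idx.size < 2:
        raise ValueError(f"chain {chain!r} has fewer than 2 residues with Cα")
    return float(np.linalg.norm(conf.xyz[idx[-1]] - conf.xyz[idx[0]]))
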