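"""Kabsch–Sander secondary-structure assignment.

Backbone H-bonds are scored with the electrostatic model
``E = 0.084 · 332 · (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol`` (r in Å),
a bond being assigned when ``E < −0.5 kcal/mol``.  From the bond pattern,
n-turns, bridges, ladders and sheets are derived with the published
priority rules and summarized into the 8-state alphabet
{H, G, I, E, B, T, S, C}; a reduced 6-class mapping (helix, β-sheet,
β-bridge, bend, turn, coil) is provided for propensity reporting.

This energetic criterion is used *only* here; all H-bond counting
elsewhere uses the strict geometric criterion of :mod:`oligotop.hbonds`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Conformation
from .hbonds import build_amide_hydrogens, strip_hydrogens

KS_COUPLING = 0.084 * 332.0     # kcal·Å/mol
KS_CUTOFF = -0.5                # kcal/mol
_MIN_CA_DIST = 0.9              # nm; donor/acceptor Cα prefilter

REDUCED = {
    "H": "helix", "G": "helix", "I": "helix",
    "E": "β-sheet", "B": "β-bridge", "S": "bend", "T": "turn", "C": "coil",
}


@dataclass
class SSAssignment:
    """Per-residue labels keyed by (chain, res_id); caps are unlabeled."""

    labels: dict[tuple[str, int], str]

    def chain_string(self, conf: Conformation, chain: str) -> str:
        keys = [k for k in conf.residue_keys() if k[0] == chain]
        return "".join(self.labels.get(k, "C") for k in keys)

    def reduced(self, fold_bend_turn_into_coil: bool = False) -> dict[tuple[str, int], str]:
        out = {k: REDUCED[v] for k, v in self.labels.items()}
        if fold_bend_turn_into_coil:
            out = {k: ("coil" if v in ("bend", "turn") else v) for k, v in out.items()}
        return out

    def fractions(self, fold_bend_turn_into_coil: bool = False) -> dict[str, float]:
        red = self.reduced(fold_bend_turn_into_coil)
        n = max(len(red), 1)
        classes = sorted(set(REDUCED.values()))
        if fold_bend_turn_into_coil:
            classes = [c for c in classes if c not in ("bend", "turn")]
        return {c: sum(v == c for v in red.values()) / n for c in classes}


class _Residues:
    """Flattened per-residue backbone coordinate table."""

    def __init__(self, conf: Conformation):
        keys = conf.residue_keys()
        self.keys = keys
        self.index = {k: i for i, k in enumerate(keys)}
        n = len(keys)
        self.N = np.full((n, 3), np.nan)
        self.CA = np.full((n, 3), np.nan)
        self.C = np.full((n, 3), np.nan)
        self.O = np.full((n, 3), np.nan)
        self.H = np.full((n, 3), np.nan)
        self.chain = np.array([k[0] for k in keys], dtype=object)
        for i, (c, r) in enumerate(keys):
            for name, arr in (("N", self.N), ("CA", self.CA), ("C", self.C),
                              ("O", self.O), ("H", self.H)):
                j = conf.atom_index(c, r, name)
                if j is not None:
                    arr[i] = conf.xyz[j]

    def complete(self, i: int) -> bool:
        return not (np.any(np.isnan(self.N[i])) or np.any(np.isnan(self.CA[i]))
                    or np.any(np.isnan(self.C[i])) or np.any(np.isnan(self.O[i])))

    def chain_neighbor(self, i: int, step: int):
        j = i + step
        if 0 <= j < len(self.keys) and self.chain[j] == self.chain[i]:
            return j
        return None


def _ks_energy(res: _Residues, donor: int, acceptor: int) -> float:
    """Kabsch–Sander H-bond energy N-H(donor) → C=O(acceptor), kcal/mol."""
    if np.any(np.isnan(res.H[donor])):
        return 0.0
    r_on = np.linalg.norm(res.N[donor] - res.O[acceptor]) * 10.0
    r_ch = np.linalg.norm(res.H[donor] - res.C[acceptor]) * 10.0
    r_oh = np.linalg.norm(res.H[donor] - res.O[acceptor]) * 10.0
    r_cn = np.linalg.norm(res.N[donor] - res.C[acceptor]) * 10.0
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:
        return -9.9  # atom overlap: treat as bonded (standard DSSP guard)
    return KS_COUPLING * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def assign_secondary_structure(conf: Conformation) -> SSAssignment:
    """8-state Kabsch–Sander assignment for every non-cap residue.

    Residues with missing backbone atoms are labeled C.  The assignment is
    a pure function of interatomic distances, hence invariant under rigid
    motion of the conformation.
    """
    # Hydrogen positions are always re-derived from the heavy-atom frame
    # (the published algorithm constructs its own amide H); file hydrogens
    # never influence the assignment.
    conf = build_amide_hydrogens(strip_hydrogens(conf), convention="robust")
    res = _Residues(conf)
    n = len(res.keys)
    labels = np.array(["C"] * n, dtype=object)
    if n == 0:
        return SSAssignment({})

    complete = np.array([res.complete(i) for i in range(n)])
    # H-bond matrix under the energetic criterion (donor -> acceptor)
    hb = np.zeros((n, n), dtype=bool)
    ca_ok = ~np.any(np.isnan(res.CA), axis=1)
    for i in range(n):
        if not (complete[i] and ca_ok[i]) or np.any(np.isnan(res.H[i])):
            continue
        d_ca = np.linalg.norm(res.CA - res.CA[i], axis=1)
        for j in np.flatnonzero((d_ca < _MIN_CA_DIST) & complete & ca_ok):
            if j == i:
                continue
            if res.chain[j] == res.chain[i] and abs(i - j) < 2:
                continue
            hb[i, j] = _ks_energy(res, i, j) < KS_CUTOFF

    def bond(d, a) -> bool:
        return d is not None and a is not None and hb[d, a]

    # --- n-turns and helices -------------------------------------------
    turn = {m: np.zeros(n, dtype=bool) for m in (3, 4, 5)}
    for m in (3, 4, 5):
        for i in range(n):
            j = i + m
            if j < n and res.chain[j] == res.chain[i] and hb[j, i]:
                turn[m][i] = True

    helix = {m: np.zeros(n, dtype=bool) for m in (3, 4, 5)}
    for m in (3, 4, 5):
        for i in range(1, n):
            if turn[m][i - 1] and turn[m][i]:
                helix[m][i: i + m] = True

    # --- bridges and ladders -------------------------------------------
    bridges: list[tuple[int, int, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            same_chain = res.chain[i] == res.chain[j]
            if same_chain and j - i < 3:
                continue
            im, ip = res.chain_neighbor(i, -1), res.chain_neighbor(i, 1)
            jm, jp = res.chain_neighbor(j, -1), res.chain_neighbor(j, 1)
            para = (bond(i, jm) and bond(jp, i)) or (bond(j, im) and bond(ip, j))
            anti = (hb[i, j] and hb[j, i]) or (bond(im, jp) and bond(jm, ip))
            if para:
                bridges.append((i, j, "P"))
            elif anti:
                bridges.append((i, j, "A"))

    bridge_set = {(i, j, t) for i, j, t in bridges}
    in_ladder = np.zeros(n, dtype=bool)
    in_bridge = np.zeros(n, dtype=bool)
    for i, j, t in bridges:
        in_bridge[i] = in_bridge[j] = True
        nxt = (i + 1, j + 1, t) if t == "P" else (i + 1, j - 1, t)
        prv = (i - 1, j - 1, t) if t == "P" else (i - 1, j + 1, t)
        if nxt in bridge_set or prv in bridge_set:
            in_ladder[i] = in_ladder[j] = True

    # --- bends -----------------------------------------------------------
    bend = np.zeros(n, dtype=bool)
    for i in range(2, n - 2):
        if res.chain[i - 2] != res.chain[i] or res.chain[i + 2] != res.chain[i]:
            continue
        if np.any(np.isnan(res.CA[[i - 2, i, i + 2]])):
            continue
        u = res.CA[i] - res.CA[i - 2]
        v = res.CA[i + 2] - res.CA[i]
        cosang = u @ v / (np.linalg.norm(u) * np.linalg.norm(v))
        if np.degrees(np.arccos(np.clip(cosang, -1, 1))) > 70.0:
            bend[i] = True

    in_turn = np.zeros(n, dtype=bool)
    for m in (3, 4, 5):
        for i in np.flatnonzero(turn[m]):
            in_turn[i + 1: i + m] = True

    # --- priority summary ------------------------------------------------
    for i in range(n):
        if not complete[i]:
            labels[i] = "C"
        elif helix[4][i]:
            labels[i] = "H"
        elif in_ladder[i]:
            labels[i] = "E"
        elif in_bridge[i]:
            labels[i] = "B"
        elif helix[3][i]:
            labels[i] = "G"
        elif helix[5][i]:
            labels[i] = "I"
        elif in_turn[i]:
            labels[i] = "T"
        elif bend[i]:
            labels[i] = "S"
        else:
            labels[i] = "C"

    return SSAssignment({k: labels[i] for i, k in enumerate(res.keys)})
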