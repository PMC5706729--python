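"""Geometric hydrogen-bond detection and bookkeeping.

A hydrogen bond is recorded when the donor–acceptor distance is below
3.5 Å and the D-H-A angle (measured at the hydrogen, 180° = linear)
exceeds 150° — both inequalities strict, as printed.  This geometric
criterion drives all H-bond counts, maps and register assignment; the
separate Kabsch–Sander energetic criterion lives in :mod:`oligotop.dssp`
and is used only inside secondary-structure assignment.  The two are never
mixed.

Sulfur is excluded as donor/acceptor by default (no sulfur participation
is observed under this criterion in the systems this package targets); a
flag re-enables it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core import Conformation

HB_DISTANCE_MAX = 3.5    # Å, donor–acceptor
HB_ANGLE_MIN = 150.0     # degrees, D-H-A at the hydrogen

#: max H–heavy-atom distance used to pair hydrogens with their donor (nm);
#: generous so that moderate coordinate noise cannot orphan a hydrogen
_COVALENT_H = 0.18


@dataclass(frozen=True)
class HBond:
    """One detected hydrogen bond (distance in Å, angle in degrees)."""

    donor_index: int
    hydrogen_index: int
    acceptor_index: int
    donor_chain: str
    donor_res: int
    acceptor_chain: str
    acceptor_res: int
    distance: float
    angle: float
    donor_moiety: str      # 'mainchain' | 'sidechain'
    acceptor_moiety: str

    @property
    def same_chain(self) -> bool:
        return self.donor_chain == self.acceptor_chain

    @property
    def contact_class(self) -> str:
        pair = {self.donor_moiety, self.acceptor_moiety}
        if pair == {"mainchain"}:
            return "MC-MC"
        if pair == {"sidechain"}:
            return "SC-SC"
        return "MC-SC"


def build_amide_hydrogens(conf: Conformation, convention: str = "bisecting") -> Conformation:
    """Return a copy with missing backbone amide hydrogens added.

    With the default ``bisecting`` convention H is placed in the
    C(prev)–N–Cα plane along the bisector of the two N-neighbor
    directions, N–H = 1.0 Å; ``robust`` averages the bisecting and
    anti-carbonyl conventions (less sensitive to coordinate noise, used
    by the secondary-structure and strand-pairing internals).  Residues
    that already carry an H, prolines, and chain-initial residues with no
    preceding carbonyl are left untouched; existing hydrogens are
    preserved bit-exactly.
    """
    from .structgen import amide_h_position, amide_h_position_robust

    names = list(conf.names)
    elements = list(conf.elements)
    res_ids = list(conf.res_ids)
    res_names = list(conf.res_names)
    chain_ids = list(conf.chain_ids)
    xyz = [row for row in conf.xyz]

    insertions = []  # (insert_after_index, position, res meta)
    for chain in conf.chains:
        keys = [k for k in conf.residue_keys(include_caps=True) if k[0] == chain]
        prev_c = prev_o = None
        for (c, r) in keys:
            rn_idx = conf.atom_index(c, r, "N")
            if conf.res_names[conf.chain_mask(c) & (conf.res_ids == r)][0] in ("ACE",):
                prev_c = conf.atom_index(c, r, "C")
                prev_o = conf.atom_index(c, r, "O")
                continue
            n_i = rn_idx
            ca_i = conf.atom_index(c, r, "CA")
            c_i = conf.atom_index(c, r, "C")
            o_i = conf.atom_index(c, r, "O")
            has_h = conf.atom_index(c, r, "H") is not None
            res_name = conf.res_names[n_i] if n_i is not None else None
            if (n_i is not None and ca_i is not None and prev_c is not None
                    and not has_h and res_name not in ("PRO", "NH2")):
                if convention == "robust" and prev_o is not None:
                    pos = amide_h_position_robust(conf.xyz[prev_c], conf.xyz[prev_o],
                                                  conf.xyz[n_i], conf.xyz[ca_i])
                else:
                    pos = amide_h_position(conf.xyz[prev_c], conf.xyz[n_i], conf.xyz[ca_i])
                insertions.append((n_i, pos, r, res_name, c))
            prev_c = c_i if c_i is not None else prev_c
            prev_o = o_i if o_i is not None else prev_o

    if not insertions:
        return conf.copy()
    for n_i, pos, r, res_name, c in sorted(insertions, reverse=True):
        names.insert(n_i + 1, "H")
        elements.insert(n_i + 1, "H")
        res_ids.insert(n_i + 1, r)
        res_names.insert(n_i + 1, res_name)
        chain_ids.insert(n_i + 1, c)
        xyz.insert(n_i + 1, pos)
    return Conformation(np.array(names, dtype=object), np.array(elements, dtype=object),
                        np.array(res_ids, dtype=int), np.array(res_names, dtype=object),
                        np.array(chain_ids, dtype=object), np.vstack(xyz))


def _donor_pairs(conf: Conformation, include_sulfur: bool) -> list[tuple[int, int]]:
    """(heavy donor, hydrogen) pairs: every H bound to N/O (or S if enabled)."""
    donors = ["N", "O"] + (["S"] if include_sulfur else [])
    h_idx = np.flatnonzero(conf.elements == "H")
    heavy_idx = np.flatnonzero(np.isin(conf.elements, donors))
    if h_idx.size == 0 or heavy_idx.size == 0:
        return []
    tree = cKDTree(conf.xyz[heavy_idx])
    dist, nearest = tree.query(conf.xyz[h_idx], k=1)
    return [(int(heavy_idx[j]), int(h)) for h, (d, j) in zip(h_idx, zip(dist, nearest))
            if d < _COVALENT_H]


def _moiety(conf: Conformation, idx: int) -> str:
    return "mainchain" if conf.is_backbone[idx] else "sidechain"


def strip_hydrogens(conf: Conformation) -> Conformation:
    """Copy of the conformation without any hydrogen atoms."""
    keep = conf.elements != "H"
    return Conformation(conf.names[keep], conf.elements[keep], conf.res_ids[keep],
                        conf.res_names[keep], conf.chain_ids[keep], conf.xyz[keep])


def detect_hbonds(conf: Conformation, include_sulfur: bool = False,
                  auto_build_h: bool = True, rebuild_amide_h: bool = False) -> list[HBond]:
    """All hydrogen bonds under the strict geometric criterion.

    Donors are X–H groups with X ∈ {N, O} (S with ``include_sulfur``);
    acceptors are oxygens (and sulfurs if enabled).  Donor and acceptor
    must belong to distinct residues.  If the conformation carries no
    hydrogens at all, backbone amide hydrogens are reconstructed first
    (``auto_build_h``).  With ``rebuild_amide_h`` input hydrogens are
    discarded and amide hydrogens re-derived from the heavy-atom frame —
    the mode used for strand pairing, where hydrogen coordinates (noisy,
    or absent from typical PDB inputs) should not drive the topology.
    """
    if rebuild_amide_h:
        conf = build_amide_hydrogens(strip_hydrogens(conf), convention="robust")
    elif auto_build_h and not np.any(conf.elements == "H"):
        conf = build_amide_hydrogens(conf)
    acceptors = ["O"] + (["S"] if include_sulfur else [])
    acc_idx = np.flatnonzero(np.isin(conf.elements, acceptors))
    pairs = _donor_pairs(conf, include_sulfur)
    if not pairs or acc_idx.size == 0:
        return []
    tree = cKDTree(conf.xyz[acc_idx])
    out: list[HBond] = []
    for d_i, h_i in pairs:
        for j in tree.query_ball_point(conf.xyz[d_i], HB_DISTANCE_MAX / 10.0):
            a_i = int(acc_idx[j])
            if a_i == d_i:
                continue
            if (conf.chain_ids[a_i] == conf.chain_ids[d_i]
                    and conf.res_ids[a_i] == conf.res_ids[d_i]):
                continue
            da = float(np.linalg.norm(conf.xyz[a_i] - conf.xyz[d_i]))
            if not da * 10.0 < HB_DISTANCE_MAX:
                continue
            v1 = conf.xyz[d_i] - conf.xyz[h_i]
            v2 = conf.xyz[a_i] - conf.xyz[h_i]
            cosang = float(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)))
            ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            if not ang > HB_ANGLE_MIN:
                continue
            out.append(HBond(
                donor_index=d_i, hydrogen_index=h_i, acceptor_index=a_i,
                donor_chain=str(conf.chain_ids[d_i]), donor_res=int(conf.res_ids[d_i]),
                acceptor_chain=str(conf.chain_ids[a_i]), acceptor_res=int(conf.res_ids[a_i]),
                distance=da * 10.0, angle=ang,
                donor_moiety=_moiety(conf, d_i), acceptor_moiety=_moiety(conf, a_i),
            ))
    return out


def classify_hbonds(hbonds: list[HBond]) -> dict[tuple[str, str], int]:
    """Tally H-bonds by moiety class and chain relationship.

    Returns a dict keyed by (class, scope) with class in
    {'MC-MC', 'MC-SC', 'SC-SC'} and scope in {'intrachain', 'interchain'}.
    """
    counts = {(cls, scope): 0
              for cls in ("MC-MC", "MC-SC", "SC-SC")
              for scope in ("intrachain", "interchain")}
    for hb in hbonds:
        scope = "intrachain" if hb.same_chain else "interchain"
        counts[(hb.contact_class, scope)] += 1
    return counts


def hbond_table(hbonds: list[HBond], conf: Conformation):
    """Per-bond table (pandas DataFrame), exportable as TSV."""
    import pandas as pd

    rows = [{
        "donor": f"{hb.donor_chain}:{hb.donor_res}:{conf.names[hb.donor_index]}",
        "hydrogen": f"{hb.donor_chain}:{hb.donor_res}:{conf.names[hb.hydrogen_index]}",
        "acceptor": f"{hb.acceptor_chain}:{hb.acceptor_res}:{conf.names[hb.acceptor_index]}",
        "distance_A": round(hb.distance, 3),
        "angle_deg": round(hb.angle, 2),
        "donor_moiety": hb.donor_moiety,
        "acceptor_moiety": hb.acceptor_moiety,
        "class": hb.contact_class,
        "scope": "intrachain" if hb.same_chain else "interchain",
    } for hb in hbonds]
    return pd.DataFrame(rows)
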