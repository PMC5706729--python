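"""Core containers for peptide conformations and ensembles.

All coordinates are stored in nanometres. A :class:`Conformation` is a flat,
array-backed record of atoms (multi-chain, caps included); an
:class:`Ensemble` is an ordered list of conformations with optional
temperature tag and per-frame ground-truth annotations (attached by the
synthetic generator, absent for real data).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Sequence

import numpy as np

# Atomic masses (u) and Bondi van der Waals radii (nm) for the elements that
# occur in capped peptides of A/G/I/L/M/T/V.
ATOMIC_MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}
VDW_RADIUS = {"H": 0.120, "C": 0.170, "N": 0.155, "O": 0.152, "S": 0.180}

#: Backbone heavy-atom names (mainchain moiety); everything else heavy is
#: sidechain.  Cap atoms count as mainchain.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})
CAP_RESNAMES = frozenset({"ACE", "NH2", "NME"})

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


def element_of(atom_name: str) -> str:
    """Infer the element from a PDB-style atom name."""
    for ch in atom_name:
        if ch.isalpha():
            return "S" if ch.upper() == "S" else ch.upper()
    raise ValueError(f"cannot infer element from atom name {atom_name!r}")


@dataclass
class Conformation:
    """All-atom coordinates of a (multi-chain) peptide system.

    Parameters
    ----------
    names, elements, res_ids, res_names, chain_ids
        Per-atom annotation arrays of equal length.  ``res_ids`` restart
        within each chain and increase strictly along it (caps included).
    xyz
        ``(n_atoms, 3)`` float array, nm.
    """

    names: np.ndarray
    elements: np.ndarray
    res_ids: np.ndarray
    res_names: np.ndarray
    chain_ids: np.ndarray
    xyz: np.ndarray

    def __post_init__(self) -> None:
        self.names = np.asarray(self.names, dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        self.res_ids = np.asarray(self.res_ids, dtype=int)
        self.res_names = np.asarray(self.res_names, dtype=object)
        self.chain_ids = np.asarray(self.chain_ids, dtype=object)
        self.xyz = np.asarray(self.xyz, dtype=float)
        n = len(self.names)
        for arr in (self.elements, self.res_ids, self.res_names, self.chain_ids):
            if len(arr) != n:
                raise ValueError("annotation arrays must have equal length")
        if self.xyz.shape != (n, 3):
            raise ValueError(f"xyz must have shape ({n}, 3)")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("coordinates must be finite")

    # ------------------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def chains(self) -> list[str]:
        """Chain ids in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chain_ids:
            seen.setdefault(c, None)
        return list(seen)

    def chain_mask(self, chain: str) -> np.ndarray:
        return self.chain_ids == chain

    @property
    def is_cap(self) -> np.ndarray:
        return np.isin(self.res_names, list(CAP_RESNAMES))

    @property
    def is_backbone(self) -> np.ndarray:
        """Mainchain moiety mask: backbone heavy atoms, amide H, cap atoms."""
        bb = np.isin(self.names, list(BACKBONE_ATOMS)) | (self.names == "H")
        return bb | self.is_cap

    @property
    def is_heavy(self) -> np.ndarray:
        return self.elements != "H"

    @property
    def masses(self) -> np.ndarray:
        return np.array([ATOMIC_MASS[e] for e in self.elements])

    # ------------------------------------------------------------------
    def residue_keys(self, include_caps: bool = False) -> list[tuple[str, int]]:
        """Ordered (chain, res_id) keys of the peptide residues."""
        keys: dict[tuple[str, int], bool] = {}
        for c, r, rn in zip(self.chain_ids, self.res_ids, self.res_names):
            keys.setdefault((c, r), rn in CAP_RESNAMES)
        return [k for k, cap in keys.items() if include_caps or not cap]

    def atom_index(self, chain: str, res_id: int, name: str) -> Optional[int]:
        hit = np.flatnonzero(
            (self.chain_ids == chain) & (self.res_ids == res_id) & (self.names == name)
        )
        return int(hit[0]) if hit.size else None

    def ca_indices(self, chain: Optional[str] = None) -> np.ndarray:
        """Indices of Cα atoms (capped groups have none), optionally per chain."""
        mask = self.names == "CA"
        if chain is not None:
            mask &= self.chain_ids == chain
        return np.flatnonzero(mask)

    def sequence(self, chain: str) -> str:
        """One-letter sequence of a chain, caps excluded."""
        letters = []
        seen: set[int] = set()
        for r, rn, c in zip(self.res_ids, self.res_names, self.chain_ids):
            if c != chain or r in seen or rn in CAP_RESNAMES:
                continue
            seen.add(r)
            letters.append(THREE_TO_ONE.get(rn, "X"))
        return "".join(letters)

    def with_xyz(self, xyz: np.ndarray) -> "Conformation":
        """Copy of this conformation with new coordinates."""
        return replace(self, xyz=np.asarray(xyz, dtype=float).copy())

    def copy(self) -> "Conformation":
        return Conformation(
            self.names.copy(), self.elements.copy(), self.res_ids.copy(),
            self.res_names.copy(), self.chain_ids.copy(), self.xyz.copy(),
        )


def concat_chains(parts: Sequence[Conformation], chain_ids: Optional[Sequence[str]] = None) -> Conformation:
    """Merge single-chain conformations into one multi-chain conformation.

    Chains are relabelled A, B, C, ... unless explicit ids are given.
    """
    if not parts:
        raise ValueError("need at least one chain")
    if chain_ids is None:
        chain_ids = [chr(ord("A") + i) for i in range(len(parts))]
    fields_ = []
    for part, cid in zip(parts, chain_ids):
        fields_.append((
            part.names, part.elements, part.res_ids, part.res_names,
            np.full(part.n_atoms, cid, dtype=object), part.xyz,
        ))
    return Conformation(*[np.concatenate([f[i] for f in fields_]) for i in range(6)])


@dataclass
class Ensemble:
    """Ordered collection of conformations, optionally temperature-tagged."""

    frames: list[Conformation] = field(default_factory=list)
    temperature: float = 310.0
    ground_truth: Optional[list] = None  # list of GroundTruth or None

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Conformation]:
        return iter(self.frames)

    def __getitem__(self, i):
        if isinstance(i, slice):
            gt = self.ground_truth[i] if self.ground_truth is not None else None
            return Ensemble(self.frames[i], self.temperature, gt)
        return self.frames[i]
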