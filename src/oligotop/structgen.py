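"""Seeded generator of synthetic peptide conformations with known topology.

The generator produces geometric idealizations of the structural repertoire
of small amyloid oligomers — β-sheet monolayers and m+n bilayers with
parallel/antiparallel strands, register shifts and imposed twist, closed
β-barrels, β-hairpins, and self-avoiding random coils — each carrying a
:class:`GroundTruth` record so that every downstream analysis stage can be
validated round-trip without running molecular dynamics.

Two construction routes coexist:

* :func:`build_chain` grows a single chain residue-by-residue from backbone
  (φ, ψ) dihedrals with standard bond lengths/angles (NeRF placement) —
  used for helices, extended strands, hairpins and coils.
* Sheet/barrel builders use an analytically flat β-strand template whose
  carbonyl and amide directions are tilted in the strand plane by half the
  rise mismatch, so that both parallel and antiparallel ladders realize the
  geometric H-bond criterion (donor–acceptor < 3.5 Å, D-H-A > 150°)
  exactly, at any register shift.  Amide hydrogens of intended donors are
  oriented at their acceptor (idealized alignment); structures are
  geometric idealizations, not energy-minimized conformers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .core import Conformation, Ensemble, ONE_TO_THREE, concat_chains, element_of

# ---------------------------------------------------------------------------
# Ideal-geometry constants (nm / degrees)

BOND_N_CA = 0.1458
BOND_CA_C = 0.1525
BOND_C_N = 0.1329
BOND_C_O = 0.1231
BOND_N_H = 0.100
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8

#: default β-strand dihedrals and sheet spacings
BETA_PHI_PSI = (-139.0, 135.0)
DEFAULT_INTERSTRAND = 0.48   # Cα–Cα spacing between H-bonded strands
DEFAULT_INTERLAYER = 1.0     # sheet-to-sheet stacking distance in a bilayer

# Flat-template parameters: backbone in the xy-plane, strand along x.
# a1/a2 are the x-projections of the N–Cα and Cα–C bonds; the rise d follows
# from the C–N bond length; TAU is the in-plane tilt of C=O and N–H that
# makes parallel ladders close (half the rise mismatch d - a1 - a2).
_A1 = 0.135
_A2 = 0.142
_H1 = math.sqrt(BOND_N_CA ** 2 - _A1 ** 2)
_H2 = math.sqrt(BOND_CA_C ** 2 - _A2 ** 2)
RISE = _A1 + _A2 + math.sqrt(BOND_C_N ** 2 - (_H1 + _H2) ** 2)
TAU = (RISE - _A1 - _A2) / 2.0
# Carbonyl/amide in-plane tilts; their sum must equal the rise mismatch
# 2·TAU for parallel ladders to close.
TAU_O = TAU
TAU_H = TAU

# Sidechain z-matrix entries: name, element, (ref grandparent, parent's
# parent, parent), bond nm, angle deg, dihedral deg.  Canonical rotamers.
SIDECHAIN_ZMATRIX: dict[str, list[tuple]] = {
    "ALA": [],
    "GLY": [],
    "VAL": [
        ("CG1", "C", ("N", "CA", "CB"), 0.1521, 110.5, 180.0),
        ("CG2", "C", ("N", "CA", "CB"), 0.1521, 110.5, -60.0),
    ],
    "ILE": [
        ("CG1", "C", ("N", "CA", "CB"), 0.1530, 110.4, 180.0),
        ("CG2", "C", ("N", "CA", "CB"), 0.1521, 110.5, -60.0),
        ("CD1", "C", ("CA", "CB", "CG1"), 0.1513, 113.8, 180.0),
    ],
    "LEU": [
        ("CG", "C", ("N", "CA", "CB"), 0.1530, 116.3, 180.0),
        ("CD1", "C", ("CA", "CB", "CG"), 0.1521, 110.7, 60.0),
        ("CD2", "C", ("CA", "CB", "CG"), 0.1521, 110.7, -60.0),
    ],
    "MET": [
        ("CG", "C", ("N", "CA", "CB"), 0.1520, 114.1, 180.0),
        ("SD", "S", ("CA", "CB", "CG"), 0.1803, 112.7, 180.0),
        ("CE", "C", ("CB", "CG", "SD"), 0.1791, 100.2, 180.0),
    ],
    "THR": [
        ("OG1", "O", ("N", "CA", "CB"), 0.1433, 109.6, -60.0),
        ("CG2", "C", ("N", "CA", "CB"), 0.1521, 110.5, 60.0),
        ("HG1", "H", ("CA", "CB", "OG1"), 0.096, 108.5, 180.0),
    ],
}

SUPPORTED_RESIDUES = frozenset("AGILMTV")


# ---------------------------------------------------------------------------
# Specs and ground truth


@dataclass(frozen=True)
class ChainSpec:
    """Sequence plus terminal caps of one peptide chain."""

    sequence: str
    n_term_cap: str = "ACE"
    c_term_cap: str = "NH2"

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        bad = set(self.sequence) - set(ONE_TO_THREE)
        if bad:
            raise ValueError(f"unknown residue letter(s): {sorted(bad)}")
        unsupported = set(self.sequence) - SUPPORTED_RESIDUES
        if unsupported:
            raise ValueError(
                f"no sidechain template for residue(s) {sorted(unsupported)}; "
                f"supported: {''.join(sorted(SUPPORTED_RESIDUES))}"
            )
        if self.n_term_cap not in ("ACE", "none"):
            raise ValueError("n_term_cap must be 'ACE' or 'none'")
        if self.c_term_cap not in ("NH2", "none"):
            raise ValueError("c_term_cap must be 'NH2' or 'none'")

    def __len__(self) -> int:
        return len(self.sequence)


WT_SPEC = ChainSpec("AIIGLMV")      # Aβ30–36 wild type
G33V_SPEC = ChainSpec("AIIVLMV")    # G33V mutant
L34T_SPEC = ChainSpec("AIIGTMV")    # L34T mutant


def register_class(orientation: str, shift: int) -> str:
    """Name the pairing class: AP0 (antiparallel in-register), P0/P1/P2
    (parallel, 0/1/2-residue shift), everything else 'other'."""
    if orientation == "antiparallel":
        return "AP0" if shift == 0 else "other"
    if orientation == "parallel" and abs(shift) in (0, 1, 2):
        return f"P{abs(shift)}"
    return "other"


@dataclass(frozen=True)
class PairingTruth:
    chain_a: str
    chain_b: str
    orientation: str     # 'parallel' | 'antiparallel'
    register: int
    register_class: str


@dataclass
class GroundTruth:
    """Construction record attached to a synthetic conformation."""

    topology: str                      # 'barrel' | 'bilayer' | 'monolayer' | 'disordered'
    layer_sizes: tuple = ()
    pairings: list[PairingTruth] = field(default_factory=list)
    twist: Optional[float] = None      # degrees, None if not applicable
    secondary_structure: Optional[dict] = None   # chain -> per-residue labels
    radius: Optional[float] = None     # realized barrel radius (nm)


# ---------------------------------------------------------------------------
# NeRF placement and dihedral-driven chain building


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom D with |CD| = bond, angle(B,C,D) and dihedral(A,B,C,D)."""
    ang = math.radians(angle_deg)
    dih = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(dih),
        bond * math.sin(ang) * math.sin(dih),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def amide_h_position(c_prev: np.ndarray, n: np.ndarray, ca: np.ndarray) -> np.ndarray:
    """Amide H on N, in the C(prev)–N–Cα plane, bisecting, N–H = 1.0 Å."""
    u1 = (c_prev - n) / np.linalg.norm(c_prev - n)
    u2 = (ca - n) / np.linalg.norm(ca - n)
    u = -(u1 + u2)
    u /= np.linalg.norm(u)
    return n + BOND_N_H * u


def amide_h_position_robust(c_prev: np.ndarray, o_prev: np.ndarray,
                            n: np.ndarray, ca: np.ndarray) -> np.ndarray:
    """Amide H from the average of the bisecting and anti-carbonyl
    conventions.  Using four heavy atoms instead of two averages their
    coordinate errors, which matters when reconstructing hydrogens on
    noisy structures; on ideal geometry the two conventions nearly agree."""
    u1 = (c_prev - n) / np.linalg.norm(c_prev - n)
    u2 = (ca - n) / np.linalg.norm(ca - n)
    bis = -(u1 + u2)
    bis /= np.linalg.norm(bis)
    anti = (c_prev - o_prev) / np.linalg.norm(c_prev - o_prev)
    u = bis + anti
    u /= np.linalg.norm(u)
    return n + BOND_N_H * u


class _ChainBuilder:
    """Accumulates atoms of one chain in order."""

    def __init__(self):
        self.names: list[str] = []
        self.elements: list[str] = []
        self.res_ids: list[int] = []
        self.res_names: list[str] = []
        self.xyz: list[np.ndarray] = []

    def add(self, name: str, res_id: int, res_name: str, pos: np.ndarray,
            element: Optional[str] = None):
        self.names.append(name)
        self.elements.append(element or element_of(name))
        self.res_ids.append(res_id)
        self.res_names.append(res_name)
        self.xyz.append(np.asarray(pos, dtype=float))

    def get(self, res_id: int, name: str) -> np.ndarray:
        for i in range(len(self.names) - 1, -1, -1):
            if self.res_ids[i] == res_id and self.names[i] == name:
                return self.xyz[i]
        raise KeyError((res_id, name))

    def to_conformation(self, chain_id: str = "A") -> Conformation:
        n = len(self.names)
        return Conformation(
            np.array(self.names, dtype=object),
            np.array(self.elements, dtype=object),
            np.array(self.res_ids, dtype=int),
            np.array(self.res_names, dtype=object),
            np.full(n, chain_id, dtype=object),
            np.vstack(self.xyz),
        )


def _attach_sidechain(builder: _ChainBuilder, res_id: int, res_name: str,
                      n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> None:
    """Place CB (tetrahedral, L-configuration) and the canonical-rotamer
    sidechain heavy atoms (plus Thr hydroxyl H) for one residue."""
    if res_name == "GLY":
        return
    b1 = (n - ca) / np.linalg.norm(n - ca)
    b2 = (c - ca) / np.linalg.norm(c - ca)
    u = -(b1 + b2)
    u /= np.linalg.norm(u)
    w = np.cross(b2, b1)
    w /= np.linalg.norm(w)
    theta = math.radians(51.7)   # gives angle(N-CA-CB) ~ 110.5 deg
    cb = ca + 0.1526 * (math.cos(theta) * u + math.sin(theta) * w)
    builder.add("CB", res_id, res_name, cb)
    coords = {"N": n, "CA": ca, "C": c, "CB": cb}
    for name, elem, (pa, pb, pc), bond, ang, dih in SIDECHAIN_ZMATRIX[res_name]:
        pos = place_atom(coords[pa], coords[pb], coords[pc], bond, ang, dih)
        coords[name] = pos
        builder.add(name, res_id, res_name, pos, element=elem)


def build_chain(spec: ChainSpec, backbone_dihedrals: Sequence[tuple[float, float]],
                chain_id: str = "A") -> Conformation:
    """Build one capped chain from per-residue (φ, ψ) dihedrals (degrees).

    All backbone atoms (N, H, Cα, C, O), sidechain heavy atoms and the
    requested ACE/NH2 caps are placed with standard bond lengths/angles;
    ω is fixed at 180° (trans peptide).
    """
    L = len(spec)
    dihedrals = [tuple(d) for d in backbone_dihedrals]
    if len(dihedrals) != L:
        raise ValueError(f"need {L} (phi, psi) pairs, got {len(dihedrals)}")

    b = _ChainBuilder()
    # Backbone trace first (residues 1..L), then caps, then H + sidechains.
    N = [None] * (L + 1)
    CA = [None] * (L + 1)
    C = [None] * (L + 1)
    O = [None] * (L + 1)
    N[1] = np.zeros(3)
    CA[1] = np.array([BOND_N_CA, 0.0, 0.0])
    ang = math.radians(ANGLE_N_CA_C)
    C[1] = CA[1] + BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    for i in range(1, L):
        phi_next = dihedrals[i][0]
        psi = dihedrals[i - 1][1]
        N[i + 1] = place_atom(N[i], CA[i], C[i], BOND_C_N, ANGLE_CA_C_N, psi)
        CA[i + 1] = place_atom(CA[i], C[i], N[i + 1], BOND_N_CA, ANGLE_C_N_CA, 180.0)
        C[i + 1] = place_atom(C[i], N[i + 1], CA[i + 1], BOND_CA_C, ANGLE_N_CA_C, phi_next)
        O[i] = place_atom(N[i], CA[i], C[i], BOND_C_O, ANGLE_CA_C_O, dihedrals[i - 1][1] + 180.0)
    O[L] = place_atom(N[L], CA[L], C[L], BOND_C_O, ANGLE_CA_C_O, dihedrals[L - 1][1] + 180.0)

    ace_c = None
    if spec.n_term_cap == "ACE":
        phi1 = dihedrals[0][0]
        ace_c = place_atom(C[1], CA[1], N[1], BOND_C_N, ANGLE_C_N_CA, phi1)
        ace_o = place_atom(CA[1], N[1], ace_c, BOND_C_O, 123.2, 0.0)
        ace_ch3 = place_atom(CA[1], N[1], ace_c, 0.1507, 116.0, 180.0)
        b.add("CH3", 0, "ACE", ace_ch3)
        b.add("C", 0, "ACE", ace_c)
        b.add("O", 0, "ACE", ace_o)

    for i in range(1, L + 1):
        res3 = ONE_TO_THREE[spec.sequence[i - 1]]
        b.add("N", i, res3, N[i])
        c_prev = ace_c if i == 1 else C[i - 1]
        if c_prev is not None and res3 != "PRO":
            b.add("H", i, res3, amide_h_position(c_prev, N[i], CA[i]))
        b.add("CA", i, res3, CA[i])
        b.add("C", i, res3, C[i])
        b.add("O", i, res3, O[i])
        _attach_sidechain(b, i, res3, N[i], CA[i], C[i])

    if spec.c_term_cap == "NH2":
        psiL = dihedrals[L - 1][1]
        nn = place_atom(N[L], CA[L], C[L], BOND_C_N, ANGLE_CA_C_N, psiL)
        h1 = place_atom(CA[L], C[L], nn, 0.101, 119.8, 0.0)
        h2 = place_atom(CA[L], C[L], nn, 0.101, 119.8, 180.0)
        b.add("N", L + 1, "NH2", nn)
        b.add("H1", L + 1, "NH2", h1)
        b.add("H2", L + 1, "NH2", h2)

    return b.to_conformation(chain_id)


# ---------------------------------------------------------------------------
# Flat β-strand template and sheet assembly


def _flat_strand(spec: ChainSpec, chain_id: str = "A") -> Conformation:
    """Analytically flat β-strand along x, backbone in the xy-plane.

    Residue i sits at x = i*RISE with its amide H and carbonyl O pointing
    to +y for even i and −y for odd i (pleat alternation); both are tilted
    by TAU along x so parallel and antiparallel ladders both close.
    Sidechains alternate above/below the plane.
    """
    L = len(spec)
    b = _ChainBuilder()
    hy = math.sqrt(BOND_N_H ** 2 - TAU_H ** 2)
    oy = math.sqrt(BOND_C_O ** 2 - TAU_O ** 2)

    def backbone(i: int):
        s = 1.0 if i % 2 == 0 else -1.0
        x = i * RISE
        n = np.array([x - _A1, s * _H1, 0.0])
        ca = np.array([x, 0.0, 0.0])
        c = np.array([x + _A2, s * _H2, 0.0])
        o = c + np.array([TAU_O, s * oy, 0.0])
        h = n + np.array([-TAU_H, s * hy, 0.0])
        return n, h, ca, c, o

    if spec.n_term_cap == "ACE":
        n1, _, ca1, c1, _ = backbone(0)
        ace_c = place_atom(c1, ca1, n1, BOND_C_N, ANGLE_C_N_CA, BETA_PHI_PSI[0])
        ace_o = place_atom(ca1, n1, ace_c, BOND_C_O, 123.2, 0.0)
        ace_ch3 = place_atom(ca1, n1, ace_c, 0.1507, 116.0, 180.0)
        b.add("CH3", 0, "ACE", ace_ch3)
        b.add("C", 0, "ACE", ace_c)
        b.add("O", 0, "ACE", ace_o)

    for i in range(L):
        res3 = ONE_TO_THREE[spec.sequence[i]]
        n, h, ca, c, o = backbone(i)
        b.add("N", i + 1, res3, n)
        b.add("H", i + 1, res3, h)
        b.add("CA", i + 1, res3, ca)
        b.add("C", i + 1, res3, c)
        b.add("O", i + 1, res3, o)
        _attach_sidechain(b, i + 1, res3, n, ca, c)

    if spec.c_term_cap == "NH2":
        nL, _, caL, cL, _ = backbone(L - 1)
        nn = place_atom(nL, caL, cL, BOND_C_N, ANGLE_CA_C_N, BETA_PHI_PSI[1])
        h1 = place_atom(caL, cL, nn, 0.101, 119.8, 0.0)
        h2 = place_atom(caL, cL, nn, 0.101, 119.8, 180.0)
        b.add("N", L + 1, "NH2", nn)
        b.add("H1", L + 1, "NH2", h1)
        b.add("H2", L + 1, "NH2", h2)

    return b.to_conformation(chain_id)


_SEAM_CORR: dict[tuple[str, int], float] = {}


def _seam_correction(orientation: str, length: int) -> float:
    """Sub-residue x-correction of the seam offset, calibrated once by
    numeric docking of two template strands: maximize the number of
    geometric H-bonds computed with *rebuilt* amide hydrogens, then their
    worst D-H-A angle.  Antiparallel seams support ladders in both
    donor directions; flat parallel seams are one-sided (three linear
    bonds), as the pleat geometry dictates."""
    key = (orientation, length)
    if key in _SEAM_CORR:
        return _SEAM_CORR[key]
    from .dssp import assign_secondary_structure
    from .hbonds import detect_hbonds

    spec = ChainSpec("A" * length, "none", "none")
    template = _flat_strand(spec)
    flip = orientation == "antiparallel"
    base = (length - 1) * RISE + (_A2 - _A1) if flip else 0.0
    best = (-1, -1, -np.inf, 0.0)
    for c in np.linspace(-0.15, 0.15, 121):
        strand_b = _place_strand(template, flip, False, base + c,
                                 DEFAULT_INTERSTRAND, "B")
        pair = concat_chains([template.copy(), strand_b], chain_ids=["A", "B"])
        hbs = [h for h in detect_hbonds(pair, rebuild_amide_h=True)
               if not h.same_chain and h.contact_class == "MC-MC"]
        if not hbs:
            continue
        # the seam must support sheet assignment (both bond directions in
        # the energetic network), then be as robust as possible under the
        # geometric criterion with reconstructed hydrogens
        n_e = sum(v == "E" for v in assign_secondary_structure(pair).labels.values())
        score = (n_e, min(len(hbs), 4), min(h.angle for h in hbs))
        if score > best[:3]:
            best = (*score, float(c))
    _SEAM_CORR[key] = best[3]
    return best[3]


_BARREL_CORR: dict[tuple[int, int, float], float] = {}

#: over-rotation of within-strand azimuth offsets when wrapping a sheet
#: into a barrel: strand centers keep exact ring closure while backbone
#: protrusions rotate further, tilting donor frames toward the curved
#: seam (1.0 = plain isometric wrap)
_WRAP_BETA = 1.0


def _wrap_sheet(xyz: np.ndarray, chain_ids: np.ndarray, strand_of_chain: dict,
                n_wrap: int, spacing: float, R: float) -> np.ndarray:
    period = n_wrap * spacing
    y_center = np.array([strand_of_chain[c] * spacing for c in chain_ids])
    y_eff = y_center + _WRAP_BETA * (xyz[:, 1] - y_center)
    theta = 2.0 * math.pi * y_eff / period
    rho = R + xyz[:, 2]
    return np.column_stack([xyz[:, 0], rho * np.sin(theta), rho * np.cos(theta)])


def _barrel_seam_correction(n_wrap: int, length: int, spacing: float) -> float:
    """Extra sub-residue seam offset for wrapped (barrel) sheets, calibrated
    once by building the ring and maximizing the H-bonds that survive the
    geometric criterion with reconstructed hydrogens (the wrap tilts the
    flat-calibrated geometry, so barrels get their own correction)."""
    key = (n_wrap, length, round(spacing, 4))
    if key in _BARREL_CORR:
        return _BARREL_CORR[key]
    from .hbonds import detect_hbonds

    spec = ChainSpec("A" * length, "none", "none")
    template = _flat_strand(spec)
    chain_ids = [chr(ord("A") + i) for i in range(n_wrap)]
    d_no = spacing - (_H1 + _H2 + math.sqrt(BOND_C_O ** 2 - TAU_O ** 2))
    R = 0.29 / (2.0 * math.sin(math.pi * d_no / (n_wrap * spacing)))
    best = (-1, -np.inf, 0.0)
    for c in np.linspace(-0.08, 0.08, 33):
        offsets = _strand_offsets(n_wrap + 1, "antiparallel", [0] * n_wrap,
                                  spacing, length, extra_correction=c)
        strands = [_place_strand(template, f, rl, x, y, cid)
                   for (f, rl, x, y), cid in zip(offsets[:-1], chain_ids)]
        flat = concat_chains(strands, chain_ids=chain_ids)
        strand_of = {cid: k for k, cid in enumerate(chain_ids)}
        conf = flat.with_xyz(_wrap_sheet(flat.xyz, flat.chain_ids, strand_of,
                                         n_wrap, spacing, R))
        hbs = [h for h in detect_hbonds(conf, rebuild_amide_h=True)
               if not h.same_chain and h.contact_class == "MC-MC"]
        if not hbs:
            continue
        score = (len(hbs), min(h.angle for h in hbs))
        if score > best[:2]:
            best = (*score, float(c))
    _BARREL_CORR[key] = best[2]
    return best[2]


def _strand_offsets(n_strands: int, orientation: str, shifts: Sequence[int],
                    spacing: float, length: int,
                    extra_correction: float = 0.0) -> list[tuple[bool, bool, float, float]]:
    """Per-strand (flipped, rolled, x_offset, y_offset) for a flat sheet.

    ``shifts[k]`` is the register shift of the seam between strands k and
    k+1.  Antiparallel seams reverse the strand direction (180° about the
    sheet normal) with zig-zagging x offsets; parallel seams translate by
    shift·RISE.  An odd register shift additionally *rolls* the next
    strand 180° about its own axis — the pleat parity of the facing
    residues flips with each one-residue slide, exactly as in real
    out-of-register sheets.
    """
    out = [(False, False, 0.0, 0.0)]
    flipped, rolled, x = False, False, 0.0
    for k in range(n_strands - 1):
        r = shifts[k]
        if orientation == "parallel":
            dx = r * RISE + _seam_correction("parallel", length) + extra_correction
            x = x + (-dx if flipped else dx)
        else:
            delta = ((length - 1 + r) * RISE + (_A2 - _A1)
                     + _seam_correction("antiparallel", length) + extra_correction)
            x = x - delta if flipped else x + delta
            flipped = not flipped
        rolled = rolled ^ ((r + (length - 1 if orientation == "antiparallel" else 0)) % 2 == 1)
        out.append((flipped, rolled, x, (k + 1) * spacing))
    return out


def _place_strand(template: Conformation, flipped: bool, rolled: bool,
                  x_off: float, y_off: float, chain_id: str) -> Conformation:
    xyz = template.xyz.copy()
    if flipped:    # 180° about the sheet normal (z): reverse strand direction
        xyz[:, 0] *= -1.0
        xyz[:, 1] *= -1.0
    if rolled:     # 180° about the strand axis (x): swap pleat faces
        xyz[:, 1] *= -1.0
        xyz[:, 2] *= -1.0
    xyz[:, 0] += x_off
    xyz[:, 1] += y_off
    conf = template.with_xyz(xyz)
    conf.chain_ids = np.full(conf.n_atoms, chain_id, dtype=object)
    return conf


def _find_stations(conf: Conformation, max_no: float = 0.32) -> list[tuple[int, int]]:
    """Intended backbone H-bond stations: (donor N index, acceptor O index)
    pairs on *different* chains with N–O below ``max_no`` nm."""
    n_idx = np.flatnonzero((conf.names == "N") & ~conf.is_cap)
    o_idx = np.flatnonzero((conf.names == "O") & ~conf.is_cap)
    stations = []
    for ni in n_idx:
        d = np.linalg.norm(conf.xyz[o_idx] - conf.xyz[ni], axis=1)
        for oi, dist in zip(o_idx, d):
            if dist < max_no and conf.chain_ids[oi] != conf.chain_ids[ni]:
                stations.append((int(ni), int(oi)))
    return stations


def _aim_hydrogens(conf: Conformation, stations: list[tuple[int, int]]) -> None:
    """Re-orient the amide H of each intended donor at its acceptor O."""
    for ni, oi in stations:
        hi = conf.atom_index(conf.chain_ids[ni], conf.res_ids[ni], "H")
        if hi is None:
            continue
        u = conf.xyz[oi] - conf.xyz[ni]
        nrm = np.linalg.norm(u)
        if nrm > 0:
            conf.xyz[hi] = conf.xyz[ni] + BOND_N_H * u / nrm


def _strand_axis(conf: Conformation, cid: str) -> np.ndarray:
    """TLS-fitted Cα axis of one strand (unit vector, +x oriented)."""
    ca = conf.xyz[conf.chain_mask(cid) & (conf.names == "CA")]
    cen = ca.mean(axis=0)
    _, _, vt = np.linalg.svd(ca - cen)
    ax = vt[0] if vt[0][0] >= 0 else -vt[0]
    return ax / np.linalg.norm(ax)


def _apply_twist(conf: Conformation, strand_chain_ids: Sequence[str], twist: float,
                 stations: Optional[list[tuple[int, int]]] = None) -> None:
    """Impose a mean neighboring-strand angle of ``twist`` degrees.

    Real twisted sheets coil their strands rather than rotating them
    rigidly; coiling (rotation of each point about the central strand axis
    by an angle proportional to its position along the strand) tilts the
    strand axes while leaving every interstrand H-bond geometrically
    intact, but the achievable tilt saturates at atan(offset/half-length).
    The requested twist is therefore realized as coil up to ~80% of that
    cap, plus a small rigid per-strand rotation for the remainder, whose
    ladder distortion stays minor.  Ground truth and the downstream
    measurement agree by construction: both are the mean acute angle
    between fitted neighboring strand axes.
    """
    if twist == 0.0:
        return
    m = len(strand_chain_ids)
    c0 = (m - 1) / 2.0
    if stations:
        idx = sorted({i for pair in stations for i in pair})
        center = conf.xyz[idx].mean(axis=0)
    else:
        center = conf.xyz[conf.names == "CA"].mean(axis=0)

    ca_mask = conf.names == "CA"
    half_len = max(np.abs(conf.xyz[ca_mask, 0] - center[0]).max(), 1e-6)
    u = {cid: conf.xyz[conf.chain_mask(cid) & ca_mask, 1].mean() - center[1]
         for cid in strand_chain_ids}
    u_vals = sorted(u.values())
    cap = 0.8 * math.degrees(
        math.atan2(0.95 * u_vals[-1], half_len)
        - math.atan2(0.95 * u_vals[0], half_len)) / max(m - 1, 1)
    theta_coil = min(twist, max(cap, 0.0))

    def coil(omega: float) -> np.ndarray:
        xyz = conf.xyz.copy()
        phi = omega * (xyz[:, 0] - center[0])
        dy = xyz[:, 1] - center[1]
        dz = xyz[:, 2] - center[2]
        xyz[:, 1] = center[1] + dy * np.cos(phi) - dz * np.sin(phi)
        xyz[:, 2] = center[2] + dy * np.sin(phi) + dz * np.cos(phi)
        return xyz

    def mean_pair_angle(xyz: np.ndarray) -> float:
        # acute angle between neighboring fitted axes: the exact quantity
        # the topology module reports as the sheet twist
        saved = conf.xyz
        conf.xyz = xyz
        axes = [_strand_axis(conf, cid) for cid in strand_chain_ids]
        conf.xyz = saved
        order = np.argsort([u[cid] for cid in strand_chain_ids])
        out = []
        for a, b in zip(order[:-1], order[1:]):
            ang = math.degrees(math.acos(np.clip(abs(axes[a] @ axes[b]), -1, 1)))
            out.append(ang)
        return float(np.mean(out))

    achieved = 0.0
    if theta_coil > 0:
        # the coil angle saturates in omega; pick the best grid point on
        # the rising branch, then refine by bisection
        grid = np.linspace(0.0, 0.95 * math.pi / 2.0 / half_len, 49)
        angles = [mean_pair_angle(coil(w)) for w in grid]
        peak = int(np.argmax(angles))
        k_best = int(np.argmin([abs(a - theta_coil) for a in angles[: peak + 1]]))
        lo = grid[max(k_best - 1, 0)]
        hi = grid[min(k_best + 1, peak)]
        for _ in range(30):
            mid = (lo + hi) / 2.0
            if mean_pair_angle(coil(mid)) < theta_coil:
                lo = mid
            else:
                hi = mid
        conf.xyz = coil((lo + hi) / 2.0)
        achieved = mean_pair_angle(conf.xyz)

    # rotation about +y by a positive angle tilts a +x axis toward -z,
    # opposing the coil tilt: negate to add; one refinement pass absorbs
    # the axis-composition nonlinearity
    for _ in range(3):
        theta_rigid = twist - mean_pair_angle(conf.xyz)
        if abs(theta_rigid) < 0.05:
            break
        for k, cid in enumerate(strand_chain_ids):
            ang = -math.radians((k - c0) * theta_rigid)
            mask = conf.chain_mask(cid)
            rel = conf.xyz[mask] - center
            cos_a, sin_a = math.cos(ang), math.sin(ang)
            x, z = rel[:, 0].copy(), rel[:, 2].copy()
            rel[:, 0] = cos_a * x + sin_a * z
            rel[:, 2] = -sin_a * x + cos_a * z
            conf.xyz[mask] = rel + center


def _sheet(spec: ChainSpec, n_strands: int, orientation: str,
           shifts: Sequence[int], twist: float, spacing: float,
           chain_ids: Sequence[str]) -> tuple[Conformation, list[PairingTruth]]:
    """Flat (optionally twisted) single β-sheet of identical strands."""
    template = _flat_strand(spec)
    offsets = _strand_offsets(n_strands, orientation, shifts, spacing, len(spec))
    strands = [_place_strand(template, f, rl, x, y, cid)
               for (f, rl, x, y), cid in zip(offsets, chain_ids)]
    conf = concat_chains(strands, chain_ids=list(chain_ids))
    stations = _find_stations(conf)
    _apply_twist(conf, chain_ids, twist, stations)
    _aim_hydrogens(conf, stations)
    pairings = [
        PairingTruth(chain_ids[k], chain_ids[k + 1], orientation, shifts[k],
                     register_class(orientation, shifts[k]))
        for k in range(n_strands - 1)
    ]
    return conf, pairings


def _normalize_shifts(register_shift, n_seams: int) -> list[int]:
    if isinstance(register_shift, (int, np.integer)):
        return [int(register_shift)] * n_seams
    shifts = [int(r) for r in register_shift]
    if len(shifts) != n_seams:
        raise ValueError(f"need {n_seams} register shifts, got {len(shifts)}")
    return shifts


def build_bilayer(spec: ChainSpec, m: int, n: int, orientation: str = "antiparallel",
                  register_shift: int | Sequence[int] = 0, twist: float = 0.0,
                  interstrand_spacing: float = DEFAULT_INTERSTRAND,
                  interlayer_spacing: float = DEFAULT_INTERLAYER,
                  ) -> tuple[Conformation, GroundTruth]:
    """m+n β-sheet bilayer (n = 0 gives a single m-stranded monolayer).

    Two stacked flat sheets separated by ``interlayer_spacing`` along the
    sheet normal; successive strands within each sheet are rotated by
    ``twist`` degrees about the stacking axis.
    """
    if m < 1 or n < 0:
        raise ValueError("need m >= 1 and n >= 0 strands")
    if orientation not in ("parallel", "antiparallel"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if interstrand_spacing < 0.4 or (n > 0 and interlayer_spacing < 0.4):
        raise ValueError("geometrically infeasible spacing (< 0.4 nm)")
    if not (0.0 <= twist <= 40.0):
        raise ValueError("twist must be within [0, 40] degrees")
    total = m + n
    chain_ids = [chr(ord("A") + i) for i in range(total)]
    shifts = _normalize_shifts(register_shift, max(m - 1, 0) + max(n - 1, 0))

    conf1, pair1 = _sheet(spec, m, orientation, shifts[: m - 1] if m > 1 else [],
                          twist, interstrand_spacing, chain_ids[:m])
    parts, pairings = [conf1], pair1
    if n > 0:
        conf2, pair2 = _sheet(spec, n, orientation, shifts[m - 1:], twist,
                              interstrand_spacing, chain_ids[m:])
        xyz2 = conf2.xyz.copy()
        xyz2[:, 2] += interlayer_spacing
        # center the smaller sheet over the larger one
        xyz2[:, 1] += (m - n) * interstrand_spacing / 2.0
        conf2 = conf2.with_xyz(xyz2)
        parts.append(conf2)
        pairings = pair1 + pair2

    full = Conformation(
        *[np.concatenate([getattr(p, f) for p in parts])
          for f in ("names", "elements", "res_ids", "res_names", "chain_ids", "xyz")]
    )
    topo = "bilayer" if n > 0 else "monolayer"
    sizes = (max(m, n), min(m, n)) if n > 0 else (m,)
    ss = {c: "E" * len(spec) for c in chain_ids}
    gt = GroundTruth(topology=topo, layer_sizes=sizes, pairings=pairings,
                     twist=twist, secondary_structure=ss)
    return full, gt


def build_barrel(spec: ChainSpec, n_strands: int = 6,
                 register_offsets: int | Sequence[int] = 0,
                 radius: Optional[float] = None,
                 orientation: str = "antiparallel",
                 interstrand_spacing: float = DEFAULT_INTERSTRAND,
                 broken_seam: bool = False,
                 ) -> tuple[Conformation, GroundTruth]:
    """Closed β-barrel: a flat sheet wrapped onto a cylinder.

    The realized radius follows from ring closure, R = n·spacing / 2π (the
    requested ``radius`` is only validated as a feasibility bound and the
    actual value is recorded in the ground truth).  Antiparallel barrels
    need an even strand count; register offsets must cancel around the ring
    (alternating sum for antiparallel seams, plain sum for parallel) for
    the barrel to close.  ``broken_seam=True`` widens one seam beyond
    H-bond range, producing an open (monolayer) sheet on the cylinder.
    """
    if n_strands < 4:
        raise ValueError("a barrel needs at least 4 strands")
    if orientation == "antiparallel" and n_strands % 2:
        raise ValueError("antiparallel barrels need an even strand count")
    shifts = _normalize_shifts(register_offsets, n_strands)
    signs = [(-1) ** k for k in range(n_strands)] if orientation == "antiparallel" \
        else [1] * n_strands
    if sum(s * r for s, r in zip(signs, shifts)) != 0:
        raise ValueError("register offsets must cancel around the ring for closure")

    n_wrap = n_strands + (1 if broken_seam else 0)
    # Radius: the ring closes at any radius (azimuths are fixed by the
    # strand count); choose it so the wrapped donor-acceptor chords land
    # at the canonical 2.9 Å rather than the compressed arc-closure value.
    d_no = interstrand_spacing - (_H1 + _H2 + math.sqrt(BOND_C_O ** 2 - TAU_O ** 2))
    R = 0.29 / (2.0 * math.sin(math.pi * d_no / (n_wrap * interstrand_spacing)))
    if radius is not None and radius < 0.7 * n_wrap * interstrand_spacing / (2.0 * math.pi):
        raise ValueError(
            f"radius {radius} nm too small for {n_strands} strands "
            f"(closure needs about {n_wrap * interstrand_spacing / (2.0 * math.pi):.2f} nm)")

    chain_ids = [chr(ord("A") + i) for i in range(n_strands)]
    # Flat sheet with a ghost copy of strand 0 appended so the closing seam
    # between strand n-1 and strand 0 gets its H-bond stations too.
    template = _flat_strand(spec)
    tune = _barrel_seam_correction(n_wrap, len(spec), interstrand_spacing) \
        if orientation == "antiparallel" else 0.0
    offsets = _strand_offsets(n_strands + 1, orientation, shifts, interstrand_spacing,
                              len(spec), extra_correction=tune)
    strands = [_place_strand(template, f, rl, x, y, cid)
               for (f, rl, x, y), cid in zip(offsets[:-1], chain_ids)]
    flat = concat_chains(strands, chain_ids=chain_ids)
    ghost = _place_strand(template, *offsets[-1], "@")
    flat_plus = concat_chains(list(strands) + [ghost], chain_ids=chain_ids + ["@"])
    stations_plus = _find_stations(flat_plus)

    # Map ghost-chain atoms back onto strand 0 (wrap identification).
    def remap(idx: int) -> int:
        if flat_plus.chain_ids[idx] != "@":
            return idx
        return int(flat.atom_index("A", int(flat_plus.res_ids[idx]),
                                   str(flat_plus.names[idx])))

    stations = []
    for ni, oi in {(remap(a), remap(b)) for a, b in stations_plus}:
        if flat.chain_ids[ni] != flat.chain_ids[oi]:
            stations.append((ni, oi))

    # Wrap: y -> azimuth (closure fixes the angular scale), sidechain
    # normal z -> radial offset.
    strand_of = {cid: k for k, cid in enumerate(chain_ids)}
    conf = flat.with_xyz(_wrap_sheet(flat.xyz, flat.chain_ids, strand_of,
                                     n_wrap, interstrand_spacing, R))
    _aim_hydrogens(conf, stations)

    pairings = [
        PairingTruth(chain_ids[k], chain_ids[(k + 1) % n_strands], orientation,
                     shifts[k], register_class(orientation, shifts[k]))
        for k in range(n_strands if not broken_seam else n_strands - 1)
    ]
    ss = {c: "E" * len(spec) for c in chain_ids}
    topo = "monolayer" if broken_seam else "barrel"
    sizes = (n_strands,) if broken_seam else ()
    gt = GroundTruth(topology=topo, layer_sizes=sizes, pairings=pairings,
                     twist=None, secondary_structure=ss, radius=R)
    return conf, gt


# ---------------------------------------------------------------------------
# Hairpins and coils

#: (φ, ψ) for the two turn residues (type I'-like turn geometry)
TURN_DIHEDRALS = ((55.0, 40.0), (80.0, 5.0))


def build_hairpin(spec: ChainSpec, turn_position: int, chain_id: str = "A") -> Conformation:
    """β-hairpin: extended arms around a two-residue turn.

    ``turn_position`` is the 1-based residue index of the first turn
    residue; the chain folds back so intrachain backbone H-bonds form
    across the turn and the end-to-end Cα distance drops below 1.2 nm.
    """
    L = len(spec)
    if L < 5:
        raise ValueError("hairpin needs at least 5 residues")
    if not (2 <= turn_position <= L - 2):
        raise ValueError(f"turn_position must be interior (2..{L - 2})")
    dihedrals = [BETA_PHI_PSI] * L
    dihedrals[turn_position - 1] = TURN_DIHEDRALS[0]
    dihedrals[turn_position] = TURN_DIHEDRALS[1]
    return build_chain(spec, dihedrals, chain_id=chain_id)


#: (φ, ψ) basin centers, half-widths and weights for coil sampling
_COIL_BASINS = (
    ((-120.0, 130.0), (30.0, 25.0), 0.45),   # β / PPII region
    ((-70.0, -35.0), (20.0, 15.0), 0.35),    # right-handed helical
    ((60.0, 45.0), (15.0, 15.0), 0.20),      # left-handed helical
)


def _clashes(conf: Conformation, min_dist: float = 0.20) -> bool:
    """Hard-sphere self-avoidance on heavy atoms of residues >= 2 apart."""
    heavy = np.flatnonzero(conf.is_heavy)
    xyz = conf.xyz[heavy]
    res = conf.res_ids[heavy]
    d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
    far = np.abs(res[:, None] - res[None, :]) >= 2
    np.fill_diagonal(d, np.inf)
    return bool(np.any(d[far] < min_dist))


def build_coil(spec: ChainSpec, seed: int, chain_id: str = "A",
               max_tries: int = 200) -> Conformation:
    """Self-avoiding random coil by rejection-sampled dihedrals."""
    rng = np.random.default_rng(seed)
    centers = np.array([b[0] for b in _COIL_BASINS])
    widths = np.array([b[1] for b in _COIL_BASINS])
    weights = np.array([b[2] for b in _COIL_BASINS])
    for _ in range(max_tries):
        which = rng.choice(len(_COIL_BASINS), size=len(spec), p=weights)
        phi_psi = centers[which] + rng.uniform(-1, 1, size=(len(spec), 2)) * widths[which]
        conf = build_chain(spec, phi_psi, chain_id=chain_id)
        if not _clashes(conf):
            return conf
    raise RuntimeError("could not generate a clash-free coil")


def build_coil_system(spec: ChainSpec, n_chains: int, seed: int,
                      box: float = 2.6) -> tuple[Conformation, GroundTruth]:
    """Several random coils placed without overlap in a cubic region —
    the 'disordered' ground-truth class."""
    rng = np.random.default_rng(seed)
    placed: list[Conformation] = []
    chain_ids = [chr(ord("A") + i) for i in range(n_chains)]
    for i, cid in enumerate(chain_ids):
        coil = build_coil(spec, int(rng.integers(2 ** 31)), chain_id=cid)
        for _ in range(500):
            # random rotation (QR of a Gaussian matrix) + random translation
            q, _r = np.linalg.qr(rng.normal(size=(3, 3)))
            if np.linalg.det(q) < 0:
                q[:, 0] *= -1
            xyz = (coil.xyz - coil.xyz.mean(axis=0)) @ q.T
            xyz += rng.uniform(0, box, size=3)
            cand = coil.with_xyz(xyz)
            ok = True
            for other in placed:
                dmin = np.min(np.linalg.norm(
                    cand.xyz[cand.is_heavy][:, None, :] -
                    other.xyz[other.is_heavy][None, :, :], axis=-1))
                if dmin < 0.25:
                    ok = False
                    break
            if ok:
                placed.append(cand)
                break
        else:
            raise RuntimeError("could not place coil without overlap")
    conf = concat_chains(placed, chain_ids=chain_ids)
    ss = {c: "C" * len(spec) for c in chain_ids}
    gt = GroundTruth(topology="disordered", secondary_structure=ss)
    return conf, gt


# ---------------------------------------------------------------------------
# Perturbation and ensembles


def perturb(conf: Conformation, amplitude: float, seed: int) -> Conformation:
    """Add an independent zero-mean Gaussian displacement to every atom.

    ``amplitude`` is the root-mean-square *displacement* of an atom in nm
    (the RMSF convention: sqrt(E|δr|²) = amplitude), i.e. each Cartesian
    component is drawn with std amplitude/√3.  Deterministic given the
    seed."""
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if amplitude == 0:
        return conf.copy()
    rng = np.random.default_rng(seed)
    sigma = amplitude / math.sqrt(3.0)
    return conf.with_xyz(conf.xyz + rng.normal(0.0, sigma, size=conf.xyz.shape))


_BUILDERS: dict[str, Callable] = {
    "bilayer": build_bilayer,
    "barrel": build_barrel,
    "coil_system": build_coil_system,
}


def make_ensemble(recipe: Sequence[tuple], temperature: float = 310.0) -> Ensemble:
    """Assemble an ensemble from (builder, params, count, noise, seed) items.

    ``builder`` is 'bilayer', 'barrel', 'coil_system' or a callable
    returning a Conformation or (Conformation, GroundTruth); ``params`` a
    kwargs dict; ``count`` frames are emitted per item, each perturbed with
    Gaussian noise of the given std (nm) under a per-frame seed derived
    from ``seed``.  Frames keep recipe order; bit-reproducible given seeds.
    """
    if not recipe:
        raise ValueError("empty recipe")
    frames: list[Conformation] = []
    truths: list[Optional[GroundTruth]] = []
    for item in recipe:
        builder, params, count, noise, seed = item
        if count < 1:
            raise ValueError("count must be >= 1")
        fn = _BUILDERS[builder] if isinstance(builder, str) else builder
        kwargs = dict(params)
        takes_seed = builder == "coil_system"
        rng = np.random.default_rng(seed)
        for j in range(count):
            sub = int(rng.integers(2 ** 31))
            if takes_seed:
                kwargs["seed"] = sub
            out = fn(**kwargs)
            conf, gt = out if isinstance(out, tuple) else (out, None)
            frames.append(perturb(conf, noise, seed=sub + 1) if noise > 0 else conf)
            truths.append(gt)
    return Ensemble(frames=frames, temperature=temperature, ground_truth=truths)
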