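"""Multi-model PDB reading/writing and tabular exports.

PDB is the interchange format (every MD package writes it): one MODEL per
frame, chain IDs A–F..., coordinates in Å on disk, converted to nm in
memory.  ACE/NH2 (and NME) residue names are recognized as terminal caps.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np

from .core import Conformation, Ensemble, element_of
from .structgen import GroundTruth


class PDBFormatError(ValueError):
    pass


def _format_atom_name(name: str) -> str:
    # Standard PDB alignment: element starts in column 14 for short names.
    return f" {name:<3s}" if len(name) < 4 else name[:4]


def write_pdb(path, data: Conformation | Ensemble) -> None:
    """Write a conformation or ensemble as a (multi-model) PDB file."""
    frames = data.frames if isinstance(data, Ensemble) else [data]
    lines: list[str] = []
    multi = len(frames) > 1
    for m, conf in enumerate(frames, start=1):
        if multi:
            lines.append(f"MODEL     {m:4d}")
        serial = 0
        for i in range(conf.n_atoms):
            serial += 1
            x, y, z = conf.xyz[i] * 10.0  # nm -> Å
            lines.append(
                f"ATOM  {serial:5d} {_format_atom_name(str(conf.names[i]))}"
                f" {str(conf.res_names[i]):<3s} {str(conf.chain_ids[i]):1s}"
                f"{int(conf.res_ids[i]):4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {str(conf.elements[i]):>2s}"
            )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_ensemble(path, temperature: float = 310.0) -> Ensemble:
    """Read a multi-model PDB file into an Ensemble (Å → nm).

    Single-model files yield a 1-frame ensemble.  Malformed ATOM records
    raise :class:`PDBFormatError` with the offending line number.
    """
    text = Path(path).read_text()
    if not text.strip():
        raise PDBFormatError(f"{path}: empty file")
    frames: list[Conformation] = []
    cur: list[tuple] = []

    def flush():
        if not cur:
            return
        names, elements, res_ids, res_names, chain_ids, xyz = zip(*cur)
        frames.append(Conformation(
            np.array(names, dtype=object), np.array(elements, dtype=object),
            np.array(res_ids, dtype=int), np.array(res_names, dtype=object),
            np.array(chain_ids, dtype=object), np.array(xyz, dtype=float),
        ))
        cur.clear()

    for ln, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec == "MODEL ":
            flush()
        elif rec == "ENDMDL":
            flush()
        elif rec in ("ATOM  ", "HETATM"):
            try:
                name = line[12:16].strip()
                res_name = line[17:20].strip()
                chain = line[21].strip() or "A"
                res_id = int(line[22:26])
                xyz = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
            except (ValueError, IndexError) as exc:
                raise PDBFormatError(f"{path}:{ln}: malformed ATOM record") from exc
            elem = line[76:78].strip() if len(line) >= 78 else ""
            if not elem:
                elem = element_of(name)
            cur.append((name, elem.capitalize().upper() if len(elem) == 1 else elem.upper(),
                        res_id, res_name, chain, np.asarray(xyz) / 10.0))
    flush()
    if not frames:
        raise PDBFormatError(f"{path}: no ATOM records found")
    return Ensemble(frames=frames, temperature=temperature)


def write_ground_truth(path, ensemble: Ensemble) -> None:
    """Sidecar TSV of per-frame construction truth (frame, chain, topology,
    register classes, twist)."""
    import pandas as pd

    rows = []
    for fi, gt in enumerate(ensemble.ground_truth or []):
        if gt is None:
            continue
        regs = ";".join(f"{p.chain_a}-{p.chain_b}:{p.register_class}" for p in gt.pairings)
        for chain in ensemble.frames[fi].chains:
            rows.append({
                "frame": fi, "chain": chain, "topology": gt.topology,
                "layer_sizes": "+".join(map(str, gt.layer_sizes)),
                "register": regs,
                "twist_deg": "" if gt.twist is None else f"{gt.twist:.2f}",
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def config_hash(cfg_dict: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
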