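"""Run configuration and the end-to-end analysis pipeline.

A :class:`RunConfig` gathers every tunable threshold (all echoed to the
log — no silent defaults), and :func:`run_pipeline` chains the stages:
secondary-structure propensities, Daura clustering with representatives,
per-frame topology/register/twist tables, contact maps, SASA,
distribution PDFs, the 2D free-energy landscape and the two-window
convergence diagnostic.  Every output is stamped with the config hash and
package version; stage failures are isolated so partial bundles survive.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .core import Ensemble
from .ensemble import (CONTACT_CUTOFF, ClusterResult, contact_maps, convergence_check,
                       daura_cluster, pdf1d, pmf2d, propensity_by_cluster, sasa,
                       sheet_angle_stats, ss_propensity)
from .geometry import end_to_end
from .hbonds import classify_hbonds, detect_hbonds
from .dssp import assign_secondary_structure
from .io import config_hash, write_pdb
from .topology import analyze_topology

log = logging.getLogger("oligotop")


@dataclass
class RunConfig:
    """All pipeline thresholds; defaults follow the conventions logged in
    the methods note."""

    input_paths: list[str] = field(default_factory=list)
    output_dir: str = "oligotop_out"
    chain_mapping: str = "fixed"          # or 'best-permutation'
    hbond_distance: float = 3.5           # Å
    hbond_angle: float = 150.0            # degrees
    contact_cutoff: float = CONTACT_CUTOFF
    cluster_cutoff: float = 0.35          # nm
    min_strand_length: int = 3
    stacking_threshold: float = 0.7       # nm
    temperature: float = 310.0            # K
    n_blocks: int = 2
    seed: int = 0

    def validate(self) -> None:
        for name in ("hbond_distance", "hbond_angle", "contact_cutoff",
                     "min_strand_length", "stacking_threshold", "temperature"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.cluster_cutoff < 0:
            raise ValueError("cluster_cutoff must be >= 0")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def analysis_dict(self) -> dict:
        """Parameters that determine the analysis (output location excluded,
        so reruns into different directories stamp identically)."""
        d = self.as_dict()
        d.pop("output_dir")
        return d

    def log_all(self) -> None:
        for k, v in sorted(self.as_dict().items()):
            log.info("config %s = %r", k, v)


def run_pipeline(cfg: RunConfig, ensemble: Optional[Ensemble] = None) -> dict:
    """Execute every analysis stage on an ensemble, writing a report bundle.

    Returns a dict of stage name → output path (or exception message for
    stages that failed; failures never abort the remaining stages).
    """
    from .io import read_ensemble

    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    cfg.log_all()
    stamp = f"# oligotop {__version__} config {config_hash(cfg.analysis_dict())}\n"

    if ensemble is None:
        frames = []
        for p in cfg.input_paths:
            frames.extend(read_ensemble(p, temperature=cfg.temperature).frames)
        ensemble = Ensemble(frames=frames, temperature=cfg.temperature)
    results: dict[str, str] = {}

    def write_tsv(name: str, df: pd.DataFrame) -> None:
        path = out / f"{name}.tsv"
        with open(path, "w") as fh:
            fh.write(stamp)
            df.to_csv(fh, sep="\t")
        results[name] = str(path)

    def stage(name):
        def deco(fn):
            try:
                fn()
                log.info("stage %s ok", name)
            except Exception as exc:  # isolate stage failures
                log.exception("stage %s failed", name)
                results[name] = f"FAILED: {exc}"
        return deco

    ss_cache = [assign_secondary_structure(c) for c in ensemble]

    @stage("propensity")
    def _propensity():
        per_res, overall = ss_propensity(ensemble, n_blocks=cfg.n_blocks, ss_cache=ss_cache)
        write_tsv("propensity_per_residue", per_res)
        write_tsv("propensity_overall", overall)

    clusters: list[ClusterResult] = []

    @stage("clusters")
    def _clusters():
        cr = daura_cluster(ensemble, cutoff=cfg.cluster_cutoff, mapping=cfg.chain_mapping)
        clusters.append(cr)
        df = pd.DataFrame({"cluster": np.arange(cr.n_clusters),
                           "center_frame": cr.centers,
                           "population": cr.populations}).set_index("cluster")
        write_tsv("clusters", df)
        centers = Ensemble([ensemble.frames[i] for i in cr.centers],
                           temperature=ensemble.temperature)
        write_pdb(out / "cluster_centers.pdb", centers)
        results["cluster_centers"] = str(out / "cluster_centers.pdb")
        write_tsv("propensity_by_cluster",
                  propensity_by_cluster(ensemble, cr, ss_cache=ss_cache))

    @stage("topology")
    def _topology():
        rows = []
        for fi, conf in enumerate(ensemble):
            ft = analyze_topology(conf, ss=ss_cache[fi],
                                  min_strand_length=cfg.min_strand_length,
                                  stacking_threshold=cfg.stacking_threshold)
            twists = ft.twists
            edges = ";".join(
                f"{ft.strands[u].chain}-{ft.strands[v].chain}:"
                f"{ft.graph.edges[u, v]['orientation'][:1].upper()}"
                f"{ft.graph.edges[u, v]['register_shift']}"
                for u, v in ft.graph.edges)
            rows.append({"frame": fi, "class": ft.label.cls,
                         "m": ft.label.layer_sizes[0] if ft.label.layer_sizes else "",
                         "n": ft.label.layer_sizes[1] if len(ft.label.layer_sizes) > 1 else "",
                         "twist_deg": f"{np.mean(twists):.2f}" if twists else "",
                         "pairings": edges})
        write_tsv("topology", pd.DataFrame(rows).set_index("frame"))

    @stage("hbonds")
    def _hbonds():
        rows = []
        for fi, conf in enumerate(ensemble):
            counts = classify_hbonds(detect_hbonds(conf))
            rows.append({"frame": fi, **{f"{cls}_{scope}": v
                                         for (cls, scope), v in counts.items()}})
        write_tsv("hbond_classes", pd.DataFrame(rows).set_index("frame"))

    @stage("contacts")
    def _contacts():
        cm = contact_maps(ensemble, cutoff=cfg.contact_cutoff)
        write_tsv("contacts_mc_mc", pd.DataFrame(cm.mc_mc, index=cm.residue_labels,
                                                 columns=cm.residue_labels))
        write_tsv("contacts_sc_sc", pd.DataFrame(cm.sc_sc, index=cm.residue_labels,
                                                 columns=cm.residue_labels))

    @stage("sasa")
    def _sasa():
        profiles = [sasa(c, normalize=True) for c in ensemble]
        per_res = pd.concat([p.per_residue for p in profiles], axis=1).mean(axis=1)
        df = per_res.rename("sasa_nm2").to_frame()
        df["total_mean"] = np.mean([p.total for p in profiles])
        df["normalized_mean"] = np.mean([p.normalized for p in profiles])
        write_tsv("sasa", df)

    @stage("pdfs")
    def _pdfs():
        e2e = [end_to_end(c, ch) for c in ensemble for ch in c.chains]
        density, edges = pdf1d(e2e, 0.05)
        write_tsv("pdf_end_to_end", pd.DataFrame(
            {"bin_left_nm": edges[:-1], "density": density}).set_index("bin_left_nm"))
        stats = sheet_angle_stats(ensemble)
        if stats["angles"].size:
            density, edges = stats["pdf"]
            df = pd.DataFrame({"bin_left_deg": edges[:-1], "density": density})
            df["parallel_fraction"] = stats["parallel_fraction"]
            df["antiparallel_fraction"] = stats["antiparallel_fraction"]
            write_tsv("pdf_sheet_angle", df.set_index("bin_left_deg"))

    @stage("pmf")
    def _pmf():
        grid = pmf2d(ensemble, T=cfg.temperature)
        df = pd.DataFrame(grid.free_energy,
                          index=pd.Index(grid.hbond_edges[:-1] + 0.5, name="n_hbonds"),
                          columns=np.round(grid.rg_edges[:-1], 4))
        write_tsv("pmf_hbonds_rg", df)

    @stage("convergence")
    def _convergence():
        half = len(ensemble) // 2
        if half >= 1 and len(ensemble) >= 2:
            rep = convergence_check(ensemble[:half], ensemble[half:])
            df = pd.DataFrame({"overlap": {k: v["overlap"] for k, v in rep.items()}})
            write_tsv("convergence", df)

    log.removeHandler(handler)
    handler.close()
    return results
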