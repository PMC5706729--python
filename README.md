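# oligotop

Topology analysis of β-sheet peptide oligomer ensembles — with a synthetic
structure generator that makes every stage verifiable.

## The problem

Small amyloid oligomers (hexamers of short fragments such as the Aβ30–36
peptide ACE-AIIGLMV-NH₂ and its G33V/L34T mutants) interconvert between a
small set of architectures: closed **β-barrels**, stacked **m+n β-sheet
bilayers** (two sheets of *m* and *n* strands), open **monolayers**,
β-hairpins and disordered coils.  Replica-exchange MD produces tens of
thousands of such conformations per system; turning them into science
requires a reproducible pipeline that detects hydrogen bonds, assigns
secondary structure, identifies strands and their pairing pattern
(parallel/antiparallel, in- or out-of-register), classifies the tertiary
topology, and summarizes the ensemble (clustering, propensities, contact
maps, SASA, free-energy landscapes).

`oligotop` implements that pipeline for multi-model PDB input, and — because
published trajectories are rarely deposited — ships a **seeded generator**
of idealized conformations with known ground truth (topology, register,
twist, secondary structure), so each analysis stage is validated round-trip
rather than by eye.

## Methods at the core

- **H-bonds** — geometric criterion: donor–acceptor distance `d(D,A) < 3.5 Å`
  and angle `∠(D-H-A) > 150°` (strict), with bookkeeping by moiety
  (MC-MC / MC-SC / SC-SC) and chain scope.
- **Secondary structure** — Kabsch–Sander: electrostatic bond energy
  `E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)` kcal/mol, bond if
  `E < −0.5`; n-turns, bridges, ladders and the 8-state alphabet
  {H,G,I,E,B,T,S,C}.
- **Topology** — strands are maximal E/B runs (≥3 residues) with
  total-least-squares axes; strand pairs with ≥2 backbone H-bonds form a
  graph whose edges carry orientation (sign of the axis dot product) and
  signed register shift (named classes AP0/P0/P1/P2); a simple cycle of ≥4
  strands winding ≈360° about a common axis is a **barrel**, otherwise the
  connected sheets are layered into **bilayer(m+n)** / **monolayer(k)** /
  **disordered**.
- **Sheet/twist angles** — angle between neighboring strand axes; the twist
  of a sheet is the mean over neighboring-pair angles with the
  supplementary angle taken when obtuse (so an antiparallel flat sheet has
  twist ≈0°, not ≈180°).
- **Ensemble statistics** — Daura neighbor-count clustering at a 0.35 nm
  Cα-RMSD cutoff (Kabsch superposition, proper rotations only), per-residue
  secondary-structure propensities with block error bars, interchain
  contact maps (0.54 nm heavy-atom cutoff), Shrake–Rupley SASA (Bondi
  radii, 1.4 Å probe), 1D PDFs, two-window convergence overlap, and 2D
  free-energy surfaces `F = −k_B T ln(P/P_max)` over (interchain H-bond
  count, radius of gyration).

## Worked example

```python
import numpy as np
from oligotop import *

ens = make_ensemble([
    ("barrel",  {"spec": WT_SPEC, "n_strands": 6}, 10, 0.02, 1),
    ("bilayer", {"spec": WT_SPEC, "m": 4, "n": 2}, 6, 0.02, 2),
    ("bilayer", {"spec": WT_SPEC, "m": 3, "n": 3, "twist": 15.0}, 4, 0.02, 3),
], temperature=310.0)

cr = daura_cluster(ens, cutoff=0.35)
print(f"{len(ens)} frames -> {cr.n_clusters} clusters")
for k in range(cr.n_clusters):
    rep = analyze_topology(ens.frames[cr.centers[k]])
    tw = f", twist {np.mean(rep.twists):.1f} deg" if rep.twists else ""
    print(f"cluster {k}: population {cr.populations[k]:.2f}, "
          f"center frame {cr.centers[k]}: {rep.label}{tw}, "
          f"registers {','.join(sorted(set(rep.edge_classes)))}")

_, overall = ss_propensity(ens)
print(f"overall beta-sheet propensity: {overall.loc['β-sheet','mean']:.3f} "
      f"+/- {overall.loc['β-sheet','err']:.3f}")
```

prints

```
20 frames -> 3 clusters
cluster 0: population 0.50, center frame 0: barrel, twist 0.7 deg, registers AP0
cluster 1: population 0.30, center frame 10: bilayer(4+2), twist 0.6 deg, registers AP0
cluster 2: population 0.20, center frame 16: bilayer(3+3), twist 15.4 deg, registers AP0
overall beta-sheet propensity: 0.981 +/- 0.019
```

Daura clustering separates the three constructed architectures exactly; the
representative of each cluster is classified back to its ground-truth
label, the 15° imposed twist is recovered within half a degree, and every
pairing is identified as in-register antiparallel (AP0) as built.  The
β-sheet propensity is near 1 because all frames are idealized sheet
conformers; mixing in `("coil_system", {...})` frames lowers it
proportionally.

The same analyses run on files:

```bash
oligotop generate --kind bilayer --m 4 --n 2 --count 20 --noise 0.02 --out ens.pdb
oligotop analyze ens.pdb --out reports/
oligotop topology ens.pdb
oligotop converge windowA.pdb windowB.pdb
```

`analyze` writes the full report bundle (propensities, clusters +
representative PDB, per-frame topology table, H-bond classes, contact
maps, SASA, PDFs, PMF grid, convergence overlaps) as TSV stamped with the
package version and a config hash.

## Layout

```
src/oligotop/
  core.py       conformation / ensemble containers
  structgen.py  synthetic generator with ground truth
  geometry.py   Kabsch superposition, RMSD, RG, end-to-end
  hbonds.py     geometric H-bond detection and classification
  dssp.py       Kabsch–Sander secondary structure
  topology.py   strands, pairing graph, register, twist, taxonomy
  ensemble.py   clustering, propensities, contacts, SASA, PMF, convergence
  io.py         multi-model PDB and tabular output
  pipeline.py   RunConfig + end-to-end report bundle
  cli.py        command-line interface
docs/methods.md     modelling and algorithmic choices in detail
```
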