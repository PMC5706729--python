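# Methods

This note records the models, conventions and numerical choices behind
`oligotop`, at the level of detail a user needs to interpret results or
challenge a design decision.

## Scope and units

All coordinates are handled in nanometres internally; PDB files are read
and written in Ångström.  Reported H-bond distances are in Å (matching how
such criteria are conventionally printed), angles in degrees, energies in
kcal/mol.  Residue labels for the seven-residue Aβ30–36 family
(AIIGLMV and its G33V/L34T variants) keep the parent-peptide numbering
A30…V36 in human-readable tables; everything internal is 1-based per
chain, with ACE = 0 and NH2 = L+1.

## Hydrogen bonds

Two H-bond definitions coexist deliberately and are never mixed:

* the **geometric criterion** — donor–acceptor distance strictly below
  3.5 Å and D-H-A angle (at the hydrogen, 180° = linear) strictly above
  150° — drives all H-bond counts, maps, and strand pairing;
* the **Kabsch–Sander energetic criterion**
  (`E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) < −0.5 kcal/mol`)
  lives only inside secondary-structure assignment, which delegates to the
  published algorithm.

Donors are N–H and O–H groups (Thr hydroxyl); acceptors are oxygens.
Sulfur is excluded on both sides by default — under this criterion sulfur
does not participate in the systems the package targets — and can be
re-enabled with a flag.

**Hydrogen reconstruction.** Amide hydrogens are often absent from PDB
input and are the least reliable coordinates when present.  Three
conventions are implemented:

* `build_amide_hydrogens(..., convention="bisecting")` (the public
  reconstruction): H in the C(prev)–N–Cα plane along the bisector,
  N–H = 1.0 Å; existing hydrogens are never touched.
* `convention="robust"`: the average of the bisecting and anti-carbonyl
  directions.  It uses four heavy atoms instead of two, which averages
  their coordinate errors; on ideal geometry the two conventions nearly
  coincide.
* The secondary-structure module always derives its own hydrogens with the
  robust convention (standard DSSP practice — deposited hydrogens never
  influence the assignment).

**Strand pairing accepts a backbone H-bond when the geometric criterion
holds with either the deposited hydrogens or robust-reconstructed ones.**
Rationale: the tertiary topology of a sheet is a property of the backbone
arrangement; it should not flip because hydrogen coordinates are noisy or
missing.  Direct H-bond *counts* (e.g. the free-energy landscape axis) use
the deposited hydrogens, reconstructing only when none exist.

## Secondary structure

Kabsch–Sander n-turns (3,4,5), parallel/antiparallel bridges, ladders and
the priority summary H > E > B > G > I > T > S > C are implemented as
published; bends are Cα(i−2)–Cα(i)–Cα(i+2) kinks above 70°.  β-bulge
linking of ladders is not implemented; on the short strands this package
targets, bulge-separated ladders do not occur.  Caps are unlabeled.  The
reduced six-class mapping is H/G/I→helix, E→β-sheet, B→β-bridge, S→bend,
T→turn, C→coil; because conventions differ on whether "coil" swallows
bend and turn, both groupings are available
(`fold_bend_turn_into_coil=True` merges them) and reports state which one
was used.

## Strands, register, topology

Strands are maximal runs of E/B labels of ≥3 residues, with an axis from a
total-least-squares line through their Cα positions, oriented N→C.  Two
strands sharing ≥2 backbone–backbone geometric H-bonds become an edge with:

* **orientation** — parallel iff the axis dot product is positive;
* **register shift** — for parallel pairs, each bond at donor→acceptor
  index offset *o* is consistent with register −o−1 or 1−o; every bond
  votes for both and the majority wins, ties broken toward smaller |shift|
  (a canonical in-register parallel ladder has offsets ±1 and register 0).
  For antiparallel pairs the register follows from the mean index *sum*
  relative to end-to-end alignment of the chains.  Named classes:
  AP0 (antiparallel in-register), P0/P1/P2 (parallel, 0/1/2-residue
  shift), everything else "other".

**Taxonomy.**  A frame is *disordered* when fewer than half its chains
contain a strand.  It is a *barrel* when the pairing graph holds a simple
cycle of ≥4 strands from distinct chains whose cycle-ordered centroids
wind 360°±60° about their common principal axis — the cycle+winding rule
is this package's operational definition of "closed barrel", validated
against its own generator.  Otherwise connected components are sheets:
one sheet → monolayer(k); two sheets whose minimal heavy-atom separation
is below the 0.7 nm stacking threshold → bilayer(m+n) with m ≥ n;
dissociated or >2 sheets → disordered.

**Sheet and twist angles.**  The angle between two strand axes lies in
[0°, 180°]; the twist of a sheet is the mean over neighboring-pair angles
with obtuse angles replaced by their supplement, hence always in
[0°, 90°] (a flat antiparallel sheet has pair angles ≈178° and twist ≈2°,
not 178°).  When a bilayer contains two sheets, both per-sheet twists are
retained and their mean reported.

## The synthetic generator

The generator exists to create testable ground truth; its products are
geometric idealizations — no force field, no minimization.

* **Dihedral route** (`build_chain`): NeRF chain growth with standard bond
  lengths/angles (N–Cα 1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å, ω = 180°),
  canonical-rotamer sidechains from per-residue z-matrices (A, G, I, L, M,
  T, V), ACE/NH2 caps.  Used for extended strands ((φ,ψ) = (−139°, +135°)),
  helices, hairpins (two extended arms around a type-I′-like turn) and
  self-avoiding coils (rejection sampling from three (φ,ψ) basins with a
  2.0 Å heavy-atom hard-sphere check).
* **Flat-template route** (sheets and barrels): an analytically flat
  strand along x with the backbone in the sheet plane, exact bond lengths,
  alternating pleat, and carbonyl/amide directions tilted in-plane by half
  the rise mismatch so that both parallel and antiparallel ladders close.
  Strand placement per seam: antiparallel seams reverse the strand
  direction; odd register shifts additionally roll the next strand 180°
  about its own axis (the facing pleat parity flips with each one-residue
  slide, as in real out-of-register sheets).  Sub-residue seam offsets are
  calibrated once per orientation by numeric docking of two template
  strands, maximizing the H-bonds that survive the geometric criterion
  with reconstructed hydrogens, with the constraint that parallel seams
  keep both donor directions (the bridge pattern secondary-structure
  assignment requires).  Amide hydrogens of intended donors are then
  oriented at their acceptors — an idealized alignment replacing the
  bisecting direction by at most ~20°.
* **Twist** is imposed as strand coiling about the central strand axis
  (which tilts the fitted axes while leaving every interstrand H-bond
  intact) up to ~80% of its geometric cap `atan(offset/half-length)`, plus
  a small rigid per-strand rotation for the remainder; the construction
  iterates until the mean neighboring-axis angle equals the request, so
  ground truth and downstream measurement agree by definition.  Large
  twists (≳25° for seven-residue strands) necessarily thin the H-bond
  ladders, exactly as in real strongly twisted sheets.
* **Barrels** wrap a flat antiparallel sheet onto a cylinder (y → azimuth,
  sidechain normal → radial offset), with a ghost copy of strand 0 so the
  closing seam receives its H-bond stations.  Ring closure fixes the
  azimuths, not the radius; the radius is chosen so the wrapped
  donor–acceptor chords land at the canonical 2.9 Å (≈0.54 nm for a
  hexamer at 0.48 nm spacing).  A user-supplied radius is validated as a
  feasibility bound only and the realized value recorded in the ground
  truth.  Antiparallel barrels need an even strand count, and register
  offsets must cancel around the ring (alternating sum zero).
  `broken_seam=True` widens one seam beyond H-bond range, producing the
  open-sheet control.
* **Thermal-noise stand-in** (`perturb`): independent Gaussian
  displacement per atom, parameterized by the RMS atomic displacement
  (sqrt(E|δr|²), the RMSF convention); per-Cartesian-component std is
  amplitude/√3.  Deterministic given the seed, as is `make_ensemble`
  (recipe + seeds → bit-identical coordinates).

**What the generator does not emulate:** solvent, sidechain rotamer
diversity, backbone flexibility within a strand, realistic turn/loop
geometry (the hairpin approximates a partially folded chain, not any
specific conformer), correlated thermal motion, or chain dissociation
kinetics.  Passing round-trip tests therefore demonstrates that the
analysis stack measures what the constructions encode — not that it
handles every pathology of real trajectories.

## Ensemble statistics

* **Daura clustering**: pairwise Cα-RMSD after Kabsch superposition
  (proper rotations enforced via the SVD determinant correction); the
  frame with the most unassigned neighbors within the cutoff (default
  0.35 nm) seeds each cluster, ties to the lowest frame index; clusters
  renumbered by descending population.  Chain mapping defaults to file
  order; `best-permutation` additionally minimizes over relabelings of
  identical-sequence chains (the implementation enumerates permutations,
  practical for ≤8 chains).
* **Propensities**: fractions over frames × (chain, residue) pooled by
  residue position; error bars are the standard deviation across block
  means (2 contiguous blocks by default, 5 as the alternative preset).
* **Contacts**: residues of distinct chains are in contact when the
  minimal heavy-atom distance between the designated moiety groups is
  below 0.54 nm (a common analysis convention; the value is logged).
  Probabilities average over frames × unordered chain pairs, symmetrized.
* **SASA**: Shrake–Rupley with Bondi radii, 0.14 nm probe, deterministic
  golden-spiral quadrature (960 points by default; the per-residue error
  versus a 10,000-point reference is below 2%).  The normalized variant
  divides a frame's total by the sum of each chain's SASA computed in
  isolation.
* **PMF**: `F = −k_B T ln(P/P_max)` with k_B = 0.0019872 kcal/(mol·K),
  integer bins on the interchain H-bond count and 0.01 nm bins on the
  radius of gyration; empty bins are NaN (flagged, never zero), the global
  minimum is exactly 0.  Whether the H-bond axis counts all interchain
  bonds or MC-MC only is selectable (default: all).
* **Convergence**: for end-to-end distance, H-bond count, RG, SASA and the
  secondary-structure class fractions, both windows' distributions and
  the overlap coefficient ∑ min(p_A, p_B) on shared bins.
* **Parallel/antiparallel split** of pooled neighboring-strand angles at
  the 90° boundary (configurable).

## Known limitations

* Registers are inferred from H-bond index offsets; for heavily trimmed
  strands (strong twist plus noise) the antiparallel register estimate can
  drift by one residue.
* The barrel definition requires a complete H-bonded cycle; a ring with
  one seam below two detected H-bonds classifies as a monolayer.
* `best-permutation` RMSD is factorial in chain count.
* The flat-template idealization slightly overstretches the strand rise
  (3.5 Å/residue) and flattens the pleat; bond lengths are exact, bond
  angles approximate.
* Periodic-boundary imaging is not performed; inputs are assumed
  whole-molecule imaged.
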