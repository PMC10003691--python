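# Methods

This note records the models implemented in `xlassembly`, the parameters
that matter, the numerical conventions, and what the synthetic test
substrate does and does not establish about real data.

## Cross-link distance budgets

A Lys–Lys cross-link identified by mass spectrometry bounds the Cα–Cα
distance of the linked residues by

    budget = spacer + 2 × side-chain allowance + dynamics allowance.

Defaults: side-chain allowance 5.5 Å per Lys, dynamics allowance 7.6 Å for
backbone flexibility. The two registered chemistries are CDI (spacer
2.6 Å, budget 21.2 Å) and DSBU (spacer 12.5 Å, budget 31.1 Å); arbitrary
chemistries can be registered with their own components. Distances are
Euclidean Cα–Cα — solvent-accessible-surface path distances are out of
scope — and the comparison is inclusive (≤), matching the "up to" reading
of the cutoffs. Reactivity is restricted to Lys by default; N-terminal
amine reactivity can be enabled and is then modelled as residue 1 of a
chain.

## Mapping onto homo-oligomers

On an assembly containing several identical copies, the copy that carried
a measured link is unknowable, so a link is mapped to *all* cross-copy
candidate pairs and scored by the minimum distance. A residue absent from
the model (or missing its Cα) makes the link unmappable; unmappable links
are excluded from the satisfaction denominator by default but always
listed, and a `count_unmappable` switch includes them for the stricter
convention. A self-link (same residue number on the same protein) is only
ever paired across copies, never with itself. Cross-link numbering can be
reconciled with model numbering through an explicit per-protein integer
offset map (`model_seq = link_res + offset`); the package deliberately
never guesses offsets.

## Pose evaluation

A pose is a proper rigid transform placing a ligand assembly in the
receptor frame. Scoring recomputes the satisfaction audit on the posed
coordinates and counts steric collisions as inter-assembly Cα pairs closer
than 3.0 Å — against a larger core assembly when one is supplied (the
situation where a docked subcomplex must also avoid the full oligomeric
core), else against the receptor. Defaults: a pose passes with ≥ 3
satisfied restraints and ≤ 0 clashes. The Cα-level clash proxy is a design
choice: it is fast, parameter-light, and sufficient to reject overlapping
rigid bodies; it does not see side-chain clashes.

Passing poses are ranked by the fixed total order (satisfied descending,
clashes ascending, pose id ascending) and cut to 30 structures so the cut
is reproducible. Clustering is agglomerative Ward linkage on the flattened
ligand Cα coordinates expressed in the receptor frame — with this feature
the Ward merge height is a rigid-motion-meaningful quantity — cut at k = 3
clusters by default. Representatives are medoids (minimum summed
within-cluster distance, ties to the lowest pose index), guaranteeing a
real pose, which matters when a representative seeds further modelling.

## Trajectory statistics

Trajectories are ordered frames over a fixed topology; multi-model PDB is
the canonical interchange format.

- **Superposition** is least-squares Kabsch via SVD with the reflection
  guard (det = +1 enforced); degenerate inputs (< 3 points, collinear
  reference) raise rather than returning an arbitrary frame.
- **RMSD series**: per-frame superposition onto a reference frame over the
  selection, then RMSD over the same selection.
- **RMSF** superposes all frames onto the mean structure (two-pass: align
  to frame 0, compute the mean, re-align to the mean) and measures the
  per-atom fluctuation about the mean position. A frame-0 reference is
  retained as an option for comparability with first-frame conventions.
- **Native contacts**: residue pairs whose minimum heavy-atom distance in
  the reference frame is ≤ 4.5 Å, with intra-chain sequence separation
  ≥ 3; Q(f) is the fraction of native pairs within tolerance × cutoff in
  frame f (tolerance 1.0 by default, so Q(0) = 1 by construction). The
  hard-cutoff convention was chosen over smooth switching functions as the
  simplest testable definition; cutoff, separation and tolerance are all
  configurable.
- **Contact maps** report per-residue-pair contact frequency across
  frames under the same minimum-heavy-atom-distance criterion.
- **H-bonds**: donors and acceptors are N/O atoms; the geometric criterion
  is donor–acceptor distance ≤ 3.5 Å plus a D–H⋯A angle ≥ 120° when a
  covalent hydrogen (≤ 1.2 Å from the donor) exists. Structures without
  hydrogens — including all synthetic substrates here — fall back to the
  distance-only criterion; occupancy is the fraction of frames satisfying
  it.

## Elastic network model

The ANM builds a 3N×3N Hessian over Cα nodes with uniform springs (spring
constant 1, cutoff 15 Å): the off-diagonal block for an interacting pair
is −γ·d dᵀ/|d|², with diagonal blocks accumulating the negatives. The full
dense eigendecomposition is returned with eigenvalues ascending;
eigenvalues below 1e-8 × the largest are flagged as rigid-body modes — six
for any connected, non-degenerate structure. A network with an isolated
node triggers a warning and the surplus zero modes are reported honestly
rather than suppressed. Note that a very floppy chain (e.g. a random coil
near the connectivity limit) can possess genuine internal modes that fall
numerically below the rigid-body threshold; null-space checks should use
well-connected structures. Mode animation displaces the equilibrium
structure sinusoidally along one non-rigid eigenvector, so frames k and
n−k mirror about the equilibrium.

## PCA

Frames are superposed onto the mean structure, flattened to 3N vectors,
centred, and decomposed by SVD; explained variances are s²/(F−1) and their
full-rank sum equals the total superposed positional variance. Output is
limited to 3 components by default. Component signs follow a deterministic
convention (the largest-magnitude coefficient is made positive) so results
are bit-stable across runs.

## Synthetic study conditions

The generators emulate the shape of the real problem at desk scale and are
pure functions of their seed:

- **Toy assemblies**: poly-alanine-like chains of 100 residues with a
  minimal N/CA/C/O backbone, in extended (3.8 Å Cα spacing), ideal-helix
  (radius 2.3 Å, rise 1.5 Å, 100°/residue) or bead-spring (3.8 Å-step
  random walk) geometry; Lys-like anchors sit at every 10th residue so
  anchor counts are closed-form. Assemblies are a receptor trimer and a
  ligand dimer with copies on a 20 Å ring — the homo-oligomer geometry that
  makes copy-ambiguity non-trivial.
- **Planted poses and links**: the planted placement parks the ligand
  beside the receptor (48 Å along x), close enough for abundant
  under-budget anchor pairs yet free of Cα clashes. True links are sampled
  from anchor pairs whose min-over-copies distance at the planted pose is
  within the DSBU budget; false positives from pairs beyond budget + 10 Å,
  so they stay unsatisfied even under the inclusive comparison.
- **Decoys**: uniform random rotations (quaternion sampling) with
  translations ≥ 50 Å (uniform in [50, 100] Å along a uniform direction)
  from the planted pose. Because the toy ligand is extended (~190 Å), a
  displaced-but-rotated pose can occasionally still reach the planted
  link residues, so a candidate decoy satisfying more than 2 planted links
  is redrawn from the same seeded stream: a decoy is, by definition,
  inconsistent with the planted truth. The default fixture uses 5 true +
  2 false links and 20 decoys.
- **Noise trajectories**: equilibrium coordinates plus iid per-axis
  Gaussian displacement with a scalar or per-atom σ profile, so the
  expected RMSF is σ√3 exactly; an optional global rigid wobble per frame
  exercises the superposition path. Default 2000 frames for fluctuation
  recovery, tens of frames for the other statistics.

What passing on this substrate shows: the geometry, counting, filtering,
clustering and spectral machinery is correct against independent oracles
and recovers planted ground truth. What it does not show: behaviour on
real force-field dynamics (correlated, anisotropic fluctuations),
side-chain packing, detector-level cross-link error modes, or docking
energetics — none of which the package computes.

## Numerical choices

- All coordinates in Å; transforms act rotation-first, x' = R x + t;
  rotations validated orthonormal with det = +1 within 1e-9 (reflections
  rejected as not rigid).
- PDB round-trips preserve topology exactly and coordinates to the 1e-3 Å
  fixed-column precision; altloc resolution keeps the highest-occupancy
  conformer, ties to label 'A'; HETATM and waters are dropped by default.
- Pose lists and transform files store 12 numbers (row-major rotation +
  translation) at full float precision so validation survives the
  round-trip.
- Deterministic orderings everywhere a cut or a tie occurs: atom selection
  follows flat (copy, chain, residue, atom) order; truncation uses the
  fixed total order above; cluster labels are renumbered by first
  occurrence in pose order.
- Problem sizes in the tests and the acceptance script (100-residue
  chains, 2–3 copies, ≤ 2000 frames, ≤ 50 ANM nodes, 20 decoys, 10 seeds)
  were chosen so every check runs in seconds while keeping each estimator
  in its well-conditioned regime.

## Known limitations

- Clash screening is Cα-only; a pose passing with 0 clashes can still have
  side-chain overlap.
- The satisfaction denominator convention (exclude vs count unmappable
  links) changes reported fractions; both are available, neither is
  canonical.
- The H-bond census without hydrogens is a donor–acceptor distance proxy
  and will overcount relative to an angle-aware criterion.
- ANM uses a uniform spring constant and a single cutoff; absolute
  eigenvalues are meaningful only up to that scale, and mode shapes, not
  frequencies, are the reliable output.
- mmCIF, crystallographic symmetry expansion, hydrogen placement and any
  physics-based sampling are out of scope.
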