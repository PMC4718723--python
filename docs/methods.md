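# Methods

## Ideal helix construction

Backbones are built residue-by-residue by internal-coordinate (NeRF-style)
chain extension: each atom is placed from the previous three by a bond
length, bond angle and dihedral. Dihedrals default to the canonical
α-helical φ = −57°, ψ = −47°, ω = 180°; bond geometry is the conventional
peptide set (N–Cα 1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å; angles 111.2°,
116.2°, 121.7°), recorded in `HelixBuildParams` so tests can pin exact
numbers. Only backbone atoms are built (poly-alanine output): every score
in the analysis is a Cα–Cα distance. The carbonyl O is placed in the
peptide plane (torsion ψ+180°) and matters only for valid PDB output.
Absolute coordinates are convention-dependent (different bond-geometry sets
shift them slightly); only distance-based statistics are comparable across
builders. The resulting helix measures 3.804 Å between consecutive Cα,
1.558 Å rise per residue, 3.62 residues per turn and a 2.27 Å Cα radius —
verified in tests against the canonical values and against gemmi's
dihedral calculator as an independent oracle.

A helix axis is the total-least-squares line through the Cα trace
(SVD of the centred coordinates), with endpoints at the projections of the
first and last Cα and the direction running N→C. `place_helix` moves an
ideal helix rigidly onto a rod: the helix is centred on the rod midpoint
(helices longer than their rod overhang symmetrically, since detected rods
underestimate helix extent at any density threshold), `register` slides it
in whole-residue rise steps, `roll` spins it about the axis, and
`direction` chooses which terminus faces which rod endpoint.

## Constraint scoring

The validation statistic mirrors standard covariance-model checking: a
coupling pair is satisfied when its Cα–Cα distance in the model is at most
15 Å; a report carries the satisfied fraction, the mean pair distance, the
violated pairs, and — separately, never silently — pairs whose residues are
absent from the model. Defaults follow the study design: top 90 intra-chain
couplings, top 6 couplings to the partner ring, minimum sequence separation
5 for same-chain pairs. Score ties in top-N selection break by residue
indices, so selection is reproducible regardless of input order.

## Rod detection

Two detectors are provided. The *components* method thresholds the map,
labels 26-connected components and keeps those whose principal-axis extent
reaches `min_length` with first-to-second singular value ratio at least
`anisotropy_min`; it is exact and cheap when helices are spatially
separated at the chosen level. Helices in van-der-Waals contact defeat any
single threshold — their densities merge into one component at every level
— so the *centerline* method extracts ridge centerlines instead: after
mild smoothing (σ = 1.2 voxels), a voxel is a centerline point when it is a
local density maximum along both cross-tube Hessian eigendirections
(sampled at 1 and 2 voxels by trilinear interpolation). Straight lines are
then fitted globally: every centerline point proposes a line along its
local tube direction, each candidate claims points within 2 Å whose own
directions agree (|cos| ≥ 0.85) and is refined by iterated PCA, and
candidates are accepted in descending-support order subject to a 4.5 Å
minimum axis separation. Evaluating all candidates on the full point set —
rather than claiming points greedily — keeps a helix's centerline intact
when a contact seam between touching tubes also produces a line; the seam
line carries less support than either flanking helix and is suppressed by
the separation rule. The pipeline retries detection at a falling threshold
ladder (0.35, 0.30, 0.25 of the kernel peak) when fewer rods than expected
appear, as a practitioner would interactively.

## Assignment search

With K segments and n ≥ K rods there are n!/(n−K)! · 2^K injective
(rod, direction) assignments; all are enumerated for K ≤ 8 (8!·2⁸ ≈ 10⁷
bounds runtime; beyond that a greedy-plus-swap heuristic is provided and
clearly labelled as such). Each geometric assignment is scored by
optimizing every helix's register and roll on discrete grids (register ±4
residues, 8 roll samples — config-exposed) by deterministic coordinate
ascent: helices are revisited in id order, each taking the option that
maximizes the full model's satisfied count (total distance, then option
order, break ties) until a sweep changes nothing, at most 4 sweeps.
Registers that would slide a helix end more than 2 Å beyond its rod are
inadmissible — the density constrains axial placement — and options that
drive Cα within 2.5 Å of a fixed partner chain are excluded as steric
clashes. Assignments are ranked by satisfied count (descending), mean pair
distance (ascending), then lexicographic assignment order, so ranking is
fully deterministic; a unique-maximizer flag records whether a single
assignment attains the top satisfied count (strict inequality on the count
only — the distance tie-break is not evidence of uniqueness).

The exhaustive search is exact but lazy: an admissible relaxation bound —
each helix pair (and each helix's partner-chain pairs) scored as if its
register/roll options were free of the other pairs' demands — is evaluated
in two vectorized stages (rod permutations first, directions second), and
only candidates whose bound reaches the current k-th best satisfied count
are scored exactly. Because the bound never underestimates, the returned
top-k equals a full scan's; the equivalence is tested both against the
unpruned code path and against an independent brute-force re-scorer that
rebuilds every model from scratch.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the study conditions: density maps on 1.64 Å
voxels at 6.4–7.4 Å resolution (each Cα contributes an isotropic Gaussian
of width σ = resolution/(π√2) — any fixed monotone convention would do, as
all comparisons are relative — plus i.i.d. Gaussian noise), coupling lists
of the top 90 pairs with a 6% false-positive fraction (true pairs drawn
from Cα–Cα ≤ 8 Å at sequence separation ≥ 5, false pairs from > 20 Å so
they genuinely violate the 15 Å check), and a six-helix subunit packed at
~9–10 Å axis spacing against an 8-fold ring. Scores are rank-consistent
placeholders, not calibrated probabilities — no error model for coupling
scores is assumed. Every generator is seed-deterministic.

The `subunit` bundle layout matters. Constraint satisfaction is invariant
under any rigid motion that maps the rod set onto itself, so a symmetric
lattice of identical helices admits mirror-image assignments that tie the
truth — an artificial degeneracy no real fold has. The stand-in therefore
models the architecture that makes the real problem well-posed: five
membrane-inserted helices in an irregular row (lateral jitter ±2 Å, axial
offsets ±3 Å, tilts up to 5°), helix 2 running horizontally along the
membrane surface above the row (it anchors direction and register for the
whole arrangement), the last two helices long and highly tilted (12–22°, a
parallel hairpin packing against the ring), and the ring itself supplying
six inter-chain anchors. Packings are resampled (deterministically within
the seed's stream) until axes keep clearance and no two helices approach
below 3.8 Å Cα–Cα — clashing ground truths would legitimize clashing
solutions. What the generator does *not* emulate: CTF effects, micrograph
noise and reconstruction artifacts (maps are idealized volumes), loop
density between helices, side-chain density, B-factor falloff, or
coupling-score calibration. Passing tests therefore demonstrate the
logic of the constraint-based assignment, not performance on real
micrographs.

## Map operations

Alignment maximizes real-space normalized cross-correlation: a coarse
search over a rotation-vector lattice (default 10° spacing, optionally
capped to a maximum angle for local alignments), an FFT translation scan
per orientation via the correlation theorem, then Nelder–Mead refinement
of all six parameters with trilinear resampling. Trilinear interpolation
is adequate at 7 Å features and deterministic. Averaging uses the unbiased
(N−1) voxelwise variance; the variance map is the heterogeneity signal —
mobile sub-structures inflate variance where they move and blur in the
mean. FSC is computed over unit-voxel-width frequency shells; both the
0.143 crossing and the value at 1/10 Å⁻¹ are reported, neither silently
chosen. Maps must share voxel size and grid shape; resampling across voxel
sizes is out of scope. MRC2014 I/O (mode 2, cubic voxels only) goes through
gemmi.

## State comparison

Superposition is least-squares (Kabsch, via scipy's rotation machinery,
reflections excluded), cross-checked in tests against a hand-written SVD
solution. The rotation part is reported as angle plus *screw axis* — the
invariant line placed in space nearest the moving set's centroid, since
inter-state motions act about axes through the structure, not the origin.
Below 0.1° the axis is reported as undefined rather than fabricated. Ring
offsets first match subunits by the best circular relabelling (an n-fold
ring has n equivalent labelings) and report the residual rotation in
(−180/n, +180/n]. Interpolated state transitions are linear in Cartesian
coordinates — chords, not arcs, flagged as non-physical and intended for
visualization; the midpoint of a 16° rotation sits cos(8°) inside the true
arc, which the tests quantify.

## Problem sizes and defaults

The recovery experiment runs 100 seeded trials of the full pipeline
(generate → render → detect → search); one trial takes ~1 s, dominated by
bound-table construction, and recovers the generating fold in 96/100
trials with the generating model satisfying 94.4% of couplings (85/90 by
construction). Map-operation analyses use 4-helix bundles in 40–48³ voxel
boxes and seven-map ensembles; alignment searches are capped at ±25° when
recovering known small rotations. The acceptance script scales the
recovery study to 60 trials and reports all headline quantities from a
single base seed.

## Known limitations

- The centerline detector assumes straight helices; strongly curved or
  kinked helices would fragment.
- Registers and rolls live on discrete grids; sub-grid placement error
  (≤ half a rise, ≤ 22.5° roll) is inherited by the final model.
- The uniqueness flag formalizes "only one orientation satisfies the
  constraints" as a strict maximizer of the satisfied count; near-ties are
  decided by mean distance and reported as non-unique.
- With fewer detected rods than segments the problem is declared
  infeasible rather than partially traced.
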