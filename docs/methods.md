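# Methods

## The perfusion model

The model approximates each artery's perfusion territory as the set of
parenchyma voxels closer to that artery's lobar branches than to any other
artery's, with distance measured between voxel centers in physical
millimetres.  This is a purely geometric surrogate for hemodynamics: it
assumes supply follows proximity, ignores collateral flow, flow rates and
vessel caliber, and treats the segmentation masks as exact.  Within those
assumptions it has two convenient exact properties: territories partition
the parenchyma (every voxel gets exactly one artery), and lobar territories
refine segmental ones (assignment is computed at lobar granularity and
merged upward through the tree, so a lobar territory can never cross its
parent segment's boundary).

The pipeline is two steps.  **Step 1 (tree labeling)**: the binary vessel
mask is thinned to a one-voxel 3D skeleton, converted to a 26-connected
weighted graph, rooted at the endpoint nearest a hilum-side hint point, and
decomposed into branches at junctions.  Generations are assigned by depth —
0 = main trunk, 1 = segmental, 2 = lobar — and every branch inherits the
segment (and lobar) id of its generation-1 (generation-2) ancestor.  The
generation at which "segmental" sits is configurable for early-bifurcating
anatomies.  **Step 2 (territory partition)**: every vessel voxel is painted
with the id of its nearest skeleton voxel; parenchyma voxels are then
assigned to the nearest painted lobar-or-deeper vessel voxel.  Trunk and
segmental-stem voxels never seed territories.

## Distance transform, ties, and the geodesic option

Euclidean distance (the default) is computed with one exact distance
transform per seed label; a voxel takes the label with the smallest squared
distance.  Squared distances within an absolute tolerance of 1e-6 mm² are
treated as ties and go to the **lowest label**, which makes results
deterministic, permutation-predictable, and immune to float rounding
differences between the transform and a brute-force check.  Distances use
voxel centers at 0-based index × spacing, so anisotropic voxels are handled
and uniformly rescaling the spacing leaves assignments unchanged.

Straight-line distance can cross outside the organ, so a geodesic metric is
offered: multi-source Dijkstra over the 26-neighborhood restricted to
parenchyma ∪ vessels, edge length = physical step length, same tie rule
applied lexicographically on (distance, label).  Domain voxels with no
reachable seed are labeled 0 and reported.  Euclidean remains the default
and the oracle-tested path; the geodesic implementation is voxel-graph
Dijkstra in Python and is intended for modest grids.

## Skeleton and tree details

- **Spur pruning**: terminal skeleton chains shorter than `prune_mm`
  (default 2.0 mm, sub-voxel artifact scale at 0.5–1 mm spacing) hanging off
  a junction are removed iteratively.
- **Cycles** (thinning artifacts): broken by repeatedly dropping the longest
  edge of a remaining cycle — the removal that perturbs root-to-leaf path
  lengths least.
- **Junction clusters**: voxels of degree ≥ 3 cluster by adjacency; cluster
  voxels belong to the parent branch; children are ordered by attachment
  position along the parent (ties by lowest voxel index), which fixes the
  1..K numbering of segment and lobar ids.
- **Junction fusion**: 3D thinning resolves an n-way branch point into
  nested bifurcations joined by stems shorter than about one vessel
  diameter.  Internal branches shorter than 1.8 × the local vessel radius
  (radius = distance from skeleton voxel to the vessel wall, from the
  mask's distance transform) are collapsed into their parent junction.
  On the phantom battery, such pseudo-stems measure 0.85–1.55 local radii
  versus ≥ 2.0 for genuine branches, so the rule separates the two cleanly.
- **Trunk-only trees** (no branch at the segmental generation) get a single
  segment on the trunk's distal half, with a warning.
- A root hint farther than 30 mm (configurable) from any skeleton voxel is
  an error; skeleton components not connected to the root are reported as
  orphans and excluded.

## The phantom

The phantom emulates what the upstream segmentation of a contrast CT would
hand the model: an axis-aligned ellipsoidal kidney (default semi-axes
40 × 26 × 22 mm at 1 mm isotropic spacing — a compact adult/porcine-scale
kidney), a hilar sinus wedge spanning a configurable fraction of the long
axis, an artery tree entering at the hilum, and a spherical tumor placed at
a signed offset from the kidney surface.  The tree grows as straight
segments: the trunk splits into exactly `n_segmental` generation-1 branches
fanned across the organ, each bifurcating `branch_depth` more times at
`branching_angle` ± jitter, with child radii following Murray's law
(`r_child = r_parent · 2^(−1/3)` at the default exponent).  Branch
endpoints are kept inside the ellipsoid shrunk by the tube radius, bending
toward the center when needed, which guarantees the rasterized vessels stay
inside kidney + sinus (+ the trunk's entry corridor).  All randomness comes
from one seeded generator, so a phantom is a pure function of its
parameters.

What the phantom does **not** emulate: CT intensities and noise, renal
pelvis concavity, venous and collecting-system trees, vessel curvature and
caliber variation, human segmental anatomy (apical/anterior/posterior/
basilar naming), accessory arteries, and deformable motion.  Passing the
phantom battery therefore demonstrates correctness of the geometry and
topology pipeline under clean segmentations, not robustness to real
segmentation noise.

Ground truth for the synthetic ligation experiment is defined with the same
territory machinery run on truth labels: vessel voxels are labeled by their
nearest truth-centerline voxel (lobar-and-deeper branches only) and
territories follow by nearest-seed assignment.  Recomputing territories
after deleting a segment's seeds reassigns exactly that segment's territory
— the synthetic analog of clamping.  The fully recovered pipeline (skeleton
→ tree → painting) reproduces these territories at dice ≈ 0.98–0.99; the
residual is a few-voxel offset of skeleton junctions relative to the true
centerline junctions near the hilum.  One-voxel erosion of a territory
lowers dice to ≈ 0.90 deterministically — for an eroded subset E ⊂ T,
dice = 2(V−S)/(2V−S) with V the territory volume and S its one-voxel
surface shell, and a ~30 ml territory at 1 mm spacing has S/V ≈ 0.17.  This
is a statement about surface-to-volume ratio at clinical voxel sizes, not
about model error.

## Planning quantities

- **Target segmental / feeding lobar arteries**: territory ids intersected
  by the tumor after physical dilation by `abut_margin_mm` (default 1 mm —
  "abutting" is not quantified in the nephrometry literature, so the margin
  is explicit and configurable).  Monotone in the margin by construction.
- **Contact surface area**: the default mesh estimator triangulates the
  0.5 iso-surface of the Gaussian-smoothed (σ = 1 voxel) tumor indicator
  via marching cubes and sums triangles whose centroids fall inside the
  kidney mask; it converges to the spherical-cap closed form 2πrh within a
  fraction of a percent at 0.5 mm spacing.  The voxel-face estimator counts
  spacing-weighted faces between tumor∩kidney and kidney∖tumor voxels and
  is a staircase **upper bound** (≈ 1.5 × for oblique interfaces).
- **Nephrometry**: Radius = maximal pairwise surface-voxel distance
  (via the convex hull); Exophytic fraction = tumor voxels outside the
  kidney mask / all tumor voxels — a volume criterion, using the kidney
  mask as the reference surface (a known limitation for pedunculated
  tumors); Nearness = minimum distance from tumor to sinus/collecting
  system; Location uses polar planes normal to the kidney's first principal
  axis at the extremes of the sinus extent, the sinus-based convention of
  the nephrometry literature.  Points follow the standard 1/2/3 tables;
  the anterior/posterior descriptor carries no points.

## Cohort statistics

For a k-level categorical predictor against a binary artery-count outcome,
the univariate logistic regression reduces to per-level 2×2 odds ratios
versus the reference level: OR = bc/ad with Wald 95% CI
exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d)).  This closed form equals the MLE of
the saturated logit fit (cross-checked against an iteratively reweighted
fit on expanded per-subject data).  Zero cells trigger the
Haldane–Anscombe 0.5 correction, flagged in the result; the bundled tables
contain none.  Report rounding is 2 decimals, round-half-even.  Of the
twelve published interval bounds the bundled tables imply, eleven reproduce
exactly; one lower bound computes to 1.4748 (→ 1.47) where the source
prints 1.48 — confirmed against an independent logit fit, and treated as a
printing artifact of the source.  Continuous predictors and the
multivariate model need patient-level data that a contingency table cannot
carry, so the module accepts only tabulated counts.

## Problem sizes and runtimes

The default phantom grid is 100 × 72 × 64 voxels at 1 mm; a full pipeline
run (skeletonize, tree, paint, territories) takes ≈ 1.5 s on one CPU.  The
validation batteries use 20 phantoms for the clamp-dice study, 30 for
segmental recovery, 200 random instances ≤ 16³ for the exhaustive
nearest-seed oracle, and 0.5 mm grids for CSA convergence — sizes chosen so
the whole suite runs in minutes while keeping every check at full fidelity.

## Known limitations

Proximity is not perfusion: watershed boundaries in real kidneys follow the
interlobar anatomy only approximately, and the model cannot represent
collateral supply or capsular feeders.  Tree labeling is purely topological
— a duplicated (accessory) renal artery appears as an orphan component
rather than a second trunk.  Dice validation here is volumetric; comparing
against projected 2D fluorescence views would require a camera model that
is out of scope.
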