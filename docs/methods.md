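# Methods

This note documents the models, parameter choices and numerical
conventions behind `tofvasc`, and what the synthetic phantoms do and do
not establish about real data.

## Grid model and conventions

All stages operate on `VolumeGrid`/`BinaryMask` objects: a 3D array
indexed `(x, y, z)` with `z` the axial slice axis, voxel-center
0-based indexing, per-axis spacing in mm, and a 4×4 voxel→world affine.
The reference geometry is the whole-body FLASH-TOF acquisition:
0.117 mm in-plane, 0.5 mm slices, 0.3 mm interslice distance (40% slice
overlap, represented in grid metadata; no slice-profile deconvolution
is attempted — the pipeline consumes reconstructed grids). Foreground
connectivity is 26-connectivity everywhere (components, skeletons,
graphs); all tie-breaks are lexicographic on `(z, y, x)` for bitwise
reproducibility.

## Preprocessing

*Body mask*: Otsu threshold over all voxels (256 equal-width bins),
closing with a radius-2 ball, 3D hole fill, largest component. Otsu
was chosen because it is parameter-free and deterministic; the radius-2
closing bridges surface noise without merging limbs.

*Normalization*: within-body intensities are rescaled linearly so the
1st/99th percentiles map to 0/1 (clipped). Percentile anchoring makes
the scale robust to the extreme inflow-bright outliers characteristic
of TOF.

*Denoising*: separable Gaussian with σ = 0.12 mm ≈ one in-plane voxel
(per-axis voxel sigma = σ/spacing, edge replication). Larger sigmas
measurably suppress one-voxel vessels; smaller ones leave speckle that
destabilizes the threshold selection below.

*Per-slice normalization*: sequential-excitation TOF suffers slice
crosstalk/saturation that multiplies each slice by a smooth factor.
Each axial slice with ≥ 50 within-body voxels is divided by its
within-body median and multiplied by the global within-body median
(scale-preserving); sparser slices are left unchanged. The median was
preferred over the mean because the sparse bright vessels within a
slice would bias a mean-based factor. The fixed stage order is
body mask → normalize → denoise → per-slice normalize.

## Vessel enhancement

The enhancer is the classic bright-tube Hessian-eigenvalue filter,
computed in physical units: Gaussian-derivative Hessians with per-axis
voxel sigma σ/spacing and σ²-normalization, eigenvalues ordered by
magnitude, response zeroed where λ₂ > 0 or λ₃ > 0.

Parameter defaults and why:

- `scales_mm = (0.12, 0.24, 0.36, 0.48)`: covers vessel radii from one
  in-plane voxel (distal branches) to ~4 voxels (aorta-caliber trunk,
  ~0.45 mm in the phantom model); the optimum scale for a tube of
  radius r is near r/√2, so 0.48 mm is needed for the trunk caliber.
- `alpha = 0.5` (plate rejection): standard value; body-boundary plates
  are additionally excluded by the body mask.
- `beta = 0.8` (blob rejection): deliberately more permissive than the
  common 0.5. With 0.5 mm slices, a thin vessel running obliquely
  through the slice stack is sampled as a dashed chain of blobs;
  strict blob rejection suppresses exactly those real branches. 0.8
  keeps them while the structure term still suppresses incoherent
  noise.
- `c` (structure sensitivity): per scale, half the maximum Hessian norm
  S within the body mask — the standard automatic setting; overridable
  via `c_mode: fixed`. A flat (constant) input short-circuits to a zero
  response.

*Support maps and fusion*: support_a is the mean of the vesselness map
over a centered, edge-renormalized window of 5 slices perpendicular to
axis a. Support maps operate on the vesselness map rather than raw
intensity so all fused maps share one semantic scale. Fusion is the
convex sum with weights (0.5, 1/6, 1/6, 1/6) — half the evidence from
local tubularity, half from slice-to-slice persistence, with no
preferred axis. Weights live in the config and are echoed into every
run manifest.

## Segmentation

The vessel mask is `fused ≥ max(t_otsu, t_percentile)` within the body.
Taking the maximum means both criteria must be met — the conservative
reading appropriate when foreground is a sub-percent minority class.
The percentile floor default is 99.0: at this resolution vessels
occupy roughly 0.5–1% of the body volume, so a 99th-percentile floor
encodes the true prevalence. This floor matters because Otsu's
criterion is bistable under such imbalance: on noisy probability maps
it collapses into the background mode (and the percentile governs),
while on very clean maps it overshoots into the vessel tail; the
hybrid keeps the workable side of both regimes. A constant
within-body map yields an empty mask with a warning rather than an
error. Components under 27 voxels (a 3×3×3 speck) are removed;
removal is strict (`< 27`), so an exactly-27-voxel component stays.

Skeletonization is topology-preserving 3D thinning (Lee's method).
Small highly symmetric blobs can be thinned away entirely; any input
component left with no skeleton voxel gets back its interior-most
voxel (maximum distance transform, lexicographic tie-break), so the
component-count invariant holds unconditionally.

## Trunk and branch levels

The skeleton becomes an undirected graph (nodes = skeleton voxels,
edges = 26-adjacent pairs weighted by physical length). Per component:

- *Trunk* = the maximum-physical-length simple path, computed exactly
  as the diameter of the component's minimum spanning tree (Kruskal
  with deterministic edge ordering; two farthest-node Dijkstra sweeps).
  Cycles are resolved by the MST for the diameter computation, but true
  26-adjacency is used during propagation. Longest-path was chosen as
  the deterministic formalization of "primary vessel path".
- *Branch levels*: trunk voxels are level 0. Iteratively, each
  connected remainder part adjacent to already-labeled voxels receives
  the level one above the smallest adjacent label, applied along its
  principal path — the longest path from its attachment; the rest of
  the part is picked up in later rounds. No voxel is ever relabeled
  (exclusion), every skeleton voxel gets exactly one level (partition),
  and every level-k branch contains a voxel 26-adjacent to level k−1.
  This reproduces hierarchical branch-order semantics: a side twig of a
  level-1 branch becomes level 2 even though the whole side subtree is
  one connected piece after trunk removal.
- The largest component is flagged as the main trunk. Stored labels
  keep true integer levels; rendering collapses ≥ 3 into one
  "higher-order" class (magenta).

These labels are heuristic and intended for qualitative QA, not as an
anatomical taxonomy.

## Synthetic phantoms

The generator emulates what the analysis actually sees, not the MR
physics: no Bloch simulation of inflow, no motion, no B1 bias field.

*Trees*: recursive binary bifurcation. Child radius = parent ×
per-child ratio (default the symmetric Murray-law factor 2^(−1/3));
child length = parent × per-child ratio with 10% lognormal-like
jitter; child direction = parent deflected by a sampled angle at a
random azimuth (children share a bifurcation plane). Recursion stops
at `max_depth` or below `min_radius_mm`. The acquisition-geometry
presets use an asymmetric parameterization — a dominant continuation
child (8° deflection, length ratio 0.6, radius ratio 0.9) and a
shorter side child (55°, length ratio 0.3, radius ratio 0.55) from a
0.45 mm-radius, 16 mm root — yielding the "main trunk with peripheral
branches" morphology of rodent abdominal TOF angiograms, with the
longest root-to-leaf path unambiguously the trunk.

*Voxelization*: vessels are capsules (cylinders with spherical caps);
the centerline is the dense axis sampling rounded to voxels (26-
connected per segment); ground-truth branch levels mirror the
principal-path semantics above on the segment tree. Segments thinner
than half the largest voxel dimension are rendered as centerline only,
with a warning. All truth is clipped to the body ellipsoid, preserving
the containment chain centerline ⊆ vessel ⊆ body.

*Intensities*: body level 0.3, vessel level 0.9 (TOF inflow contrast
must be positive), tanh partial-volume edges of ~1 voxel, per-slice
multiplicative drift as a smoothed, zero-centered bounded random walk
in [1−a, 1+a] with a = 0.2 (crosstalk in sequential excitation is
slice-order-correlated, not periodic), additive Gaussian noise
σ = 0.05 by default (Rician available, since magnitude MR noise is
Rician; Gaussian is the default for analytic transparency). The tumor
is a mask-only ellipsoid adjacent to a mid-tree segment — the pipeline
never uses tumor intensity.

*Presets*: `small` (64³ at 0.2 mm isotropic, depth-2 tree) for fast
tests; `default` (128×128×96 at 0.117/0.117/0.5 mm, depth-4 tree) —
the acquisition geometry; `stress` (depth-6, doubled noise).

Passing on these phantoms demonstrates correct mechanics and
sensible recovery under the modeled degradations; it does not
establish performance on real animals, where motion, bias fields,
non-elliptical anatomy and true vessel tortuosity are present.

## Evaluation

Dice on vessel masks (defined 1.0 for two empty masks); centerline
precision/recall as the fraction of predicted (resp. true) voxels
within a physical tolerance of the other set, via Euclidean distance
transforms with the grid spacing as sampling; default tolerance 1.0 mm
= 2× the largest voxel dimension, because one-voxel skeleton jitter is
expected from thinning. Branch-level agreement matches each predicted
skeleton voxel to its nearest true centerline voxel within tolerance
(unmatched voxels counted and excluded), compares levels after
collapsing ≥ 3, and reports the confusion matrix, accuracy, and trunk
overlap (recall of true level-0 by predicted level-0). An empty
prediction yields NaN precision (flagged) and zero recall. Group
summaries report n (non-missing), mean and median per group and
endpoint — descriptive statistics only, deliberately without
inferential tests.

## Problem sizes and determinism

The shipped analyses and checks use the `default` 128×128×96 preset
(one pipeline run ≈ 5 s on one CPU) and batches of `small` phantoms
for property tests; oracle comparisons use 200 random multisets (Otsu)
and 50 random ≤ 200-node trees (trunk diameter). Every random draw is
seeded; identical inputs and config give byte-identical masks, label
volumes and (timing metadata aside) manifests. Wall-clock timings are
stored under a separate `timing` key in the manifest precisely so the
rest of the manifest is a pure function of inputs and config.

## Known limitations

- The interactive human-in-the-loop QA of the original workflow is
  replaced by static MIP renders plus the run manifest; no numeric QA
  score is defined.
- Tumor masks are resampled by header affine only (nearest-neighbour);
  no image-to-image registration.
- Thin oblique vessels near one voxel in caliber are genuinely hard at
  this anisotropy: recall of distal branches, not trunk recovery, is
  the binding constraint, and some sub-slice branches are missed —
  consistent with the qualitative character of the original analysis.
- Otsu's threshold under extreme class imbalance is used only inside
  the max() hybrid; on its own it is unreliable in this regime (see
  Segmentation).
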