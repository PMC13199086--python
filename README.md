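# tofvasc

Qualitative vascular analysis for whole-body time-of-flight (TOF) MR
angiography of small animals, with synthetic phantoms that make every
stage quantitatively testable.

In 2D multi-slice FLASH-TOF angiography, inflowing blood appears bright
against saturated static tissue, so vessels can be imaged without
contrast agents. Whole-body acquisitions in mice (0.117 × 0.117 mm²
in-plane, 0.5 mm slices with overlap) pose three characteristic
problems: vessels occupy well under 1% of the body volume, voxels are
~4× anisotropic so thin oblique vessels appear as dashed chains of
blobs, and sequential slice excitation causes crosstalk/saturation that
modulates per-slice intensity. `tofvasc` implements a rule-based
pipeline for this regime:

1. **Whole-body masking** — Otsu threshold, morphological closing, 3D
   hole fill, largest 26-connected component.
2. **Preprocessing** — robust percentile normalization to [0, 1] within
   the body, 3D Gaussian denoising, and per-slice intensity
   normalization (each axial slice rescaled so its within-body median
   matches the global median) to remove slice crosstalk drift.
3. **Vessel enhancement** — multiscale Hessian vesselness for bright
   tubes. With eigenvalues |λ₁| ≤ |λ₂| ≤ |λ₃| of the σ²-normalized
   Hessian (computed in physical units on the anisotropic grid), and

       R_A = |λ₂|/|λ₃|,  R_B = |λ₁|/√(|λ₂λ₃|),  S = √(λ₁²+λ₂²+λ₃²),

   the per-scale response is
   (1 − e^(−R_A²/2α²)) · e^(−R_B²/2β²) · (1 − e^(−S²/2c²)), zero where
   λ₂ > 0 or λ₃ > 0, maximized over scales. Orthogonal-plane support
   maps (sliding slab means of the vesselness map perpendicular to each
   axis) reward slice-to-slice persistence and are fused with the
   vesselness map by a convex weighted sum into one probability volume.
4. **Segmentation & skeletonization** — hybrid threshold
   max(Otsu, percentile) of within-body fused values, small-component
   removal, topology-preserving 3D thinning.
5. **Branch-level labeling** — the skeleton becomes a voxel graph; each
   component's trunk (primary vessel path) is its maximum-physical-length
   path (exact MST diameter); branches are reconstructed outward level by
   level without voxel reuse. QA renders color the trunk red, first-order
   branches green, second-order blue, higher orders magenta, and the
   tumor overlay purple.

Because no animal data ship with the package, a seeded phantom
generator (`tofvasc.synthetic`) produces TOF-like volumes on the
acquisition geometry — body ellipsoid, trunk-dominant bifurcating
vessel trees with Murray-law taper, soft partial-volume edges, bounded
multiplicative slice drift, Gaussian or Rician noise — together with
exact ground-truth masks, centerlines and branch levels, so recovery
can be scored (Dice, tolerance-based centerline precision/recall,
trunk overlap, branch-level confusion).

## Worked example

```bash
tofvasc simulate --preset default --seed 42 --outdir results/phantom
tofvasc run results/phantom/volume.nii.gz --outdir results/run
tofvasc evaluate --pred results/run --truth results/phantom --out results/metrics.json
```

or equivalently `python analysis/01_simulate_phantom.py` through
`04_group_summary.py`. The run prints

```
threshold used 0.064 (otsu 0.027, percentile 0.064)
vessel voxels 4526, skeleton voxels 221
per-level skeleton voxels: {'0': 163, '1': 58}
Dice 0.696 | centerline precision 0.710 recall 0.848 @ 1.0 mm |
trunk overlap 0.989 | level accuracy 0.822 on 157 matched voxels
```

meaning: on the 128×128×96 acquisition-geometry phantom the hybrid
threshold was driven by the 99th-percentile floor (the Otsu term
collapsed into the background mode, as expected under extreme class
imbalance); the recovered vessel mask overlaps truth at Dice 0.70; 85%
of true centerline voxels lie within 1 mm of the recovered skeleton;
the main trunk is recovered almost completely; and 82% of matched
skeleton voxels receive the correct hierarchical branch level.

`analysis/04_group_summary.py` additionally builds a small synthetic
cohort, exports per-animal endpoints as CSV, and summarizes them per
group with n/mean/median — the descriptive-statistics path used for
group-level TOF endpoints.

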