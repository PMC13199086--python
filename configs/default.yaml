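# Frozen default configuration for the vessel-analysis pipeline.
# Every parameter consumed by any stage is materialized here and echoed
# into the run manifest; parameters were fixed after method development
# and are not tuned per dataset.

preprocess:
  close_radius_vox: 2          # body-mask morphological closing ball (voxels)
  denoise_sigma_mm: 0.12       # ~1 in-plane voxel at FLASH-TOF resolution
  robust_percentiles: [1, 99]  # robust rescaling to [0, 1] within the body
  min_slice_mask_voxels: 50    # slices with fewer body voxels skip normalization

vesselness:
  scales_mm: [0.12, 0.24, 0.36, 0.48]  # covers 1-4 voxel vessel radii
  alpha: 0.5                   # plate rejection sensitivity
  beta: 0.8                    # blob rejection, relaxed for thick-slice grids
  c_mode: auto                 # c = half max Hessian norm within the body mask

fusion:
  support_window_slices: 5     # orthogonal-plane support slab thickness
  weights: [0.5, 0.16666666666666666, 0.16666666666666666, 0.16666666666666666]

segment:
  percentile: 99.0             # vessel prevalence floor (~1% of body volume)
  min_component_voxels: 27     # 3x3x3 speckle floor
  histogram_bins: 256

evaluate:
  tolerance_mm: 1.0            # 2x the largest voxel dimension

seed: 0
log_level: INFO
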