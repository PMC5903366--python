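{
  "description": "SyN registration parameters used to build the CIT168 bivariate (T1w+T2w) group template with ANTs v2.1.0 (antsMultivariateTemplateConstruction.sh). Recorded for users driving an external diffeomorphic backend; atlasforge applies, but does not optimize, diffeomorphic transforms.",
  "algorithm": "SyN (symmetric normalization)",
  "similarity": "joint cross-correlation over T1w and T2w, equal weights",
  "syn_gradient_step": 0.25,
  "syn_gaussian_regularization_sigma_voxels": 3.0,
  "multiscale_downsampling_factors": [4, 2, 1],
  "affine_iterations_per_level": [10000, 10000, 1000],
  "syn_iterations_per_level": [30, 90, 20],
  "template_refinement_iterations": 4,
  "template_resolution_mm": 0.7
}
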