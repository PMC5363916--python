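# Default study configuration: normalized-intensity thresholds, μCT
# mineralization threshold, imaging geometry, and phantom conditions.
seed: 0
days: [10, 14, 21]
n_per_day: 5
thresholds:
  bone: [1.0, 3.4]
  fibrous_or_marrow: [3.4, 5.5]
  cartilage: [5.5, 6.2]
  fold_sub_bone: true
uct_threshold: 642.0
stats:
  paired: true
  alpha: 0.05
phantom:
  mri_spacing: [52.0, 52.0, 350.0]
  mri_shape: [128, 128, 22]
  uct_spacing: [8.0, 8.0, 8.0]
  noise_sigma: 0.05
  coil_gradient_amplitude: 0.1
  artifact_count: 4
  artifact_radius: 150.0
intensity_model: {}
vary_specimens: true
save_volumes: false
verbosity: 1
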