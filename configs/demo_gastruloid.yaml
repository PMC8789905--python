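# Demonstration configuration for the full synthetic pipeline.
# All rates and render settings are artifact defaults (the experiments the
# package emulates report no kinetic parameters); see docs/methods.md.
seed: 1
out_dir: results/pipeline_demo

sim:
  colony_radius_um: 150.0     # scaled-down colony keeps the demo fast
  cell_diameter_um: 10.0
  t_max_h: 20.0
  sample_interval_h: 2.0
  genotypes: [WT, L12KO]
  threshold: 0.5

render:
  shape_px: [240, 240]
  um_per_px: 1.5
  background: 10.0
  gain: 100.0
  psf_sigma_um: 1.0
  poisson_noise: true
  read_noise_sd: 2.0
  n_colonies: 3

prep:
  background_method: morphological_open
  background_radius_um: 50.0
  outlier_radius_px: 2
  outlier_k_sd: 5.0

colony:
  bin_width_um: 10.0
  kymograph_segments: 12

juxta:
  bin_width_um: 5.0
  lambda_um: 60.0
  amplitude: 100.0
  offset: 10.0
  band_width_um: 9.0
  band_amplitude: 80.0
  border_x_um: 180.0
  cell_diameter_um: 10.0
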