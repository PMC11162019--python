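scene:
  extent:
  - 0.0
  - 0.0
  - 1200.0
  - 800.0
  cell_size: 20.0
  relief_amplitude: 8.0
  correlation_length: 300.0
  stem_density: 550.0
  dbh_shape: 1.3
  dbh_scale: 11.0
  min_dbh: 5.0
  h_max: 22.0
  dbh_half: 16.0
  height_noise_sd: 1.0
  allometry_a: 0.0613
  allometry_b: 0.976
  fertility_strength: 0.6
  fertility_length: 250.0
  n_blocks: 2
  block_area_range:
  - 16.0
  - 16.0
  block_aspect_range:
  - 0.6
  - 1.6
  plots_per_block:
  - 10
  - 10
  plot_spacing: 100.0
  border_buffer: 50.0
  plot_radius: 10.0
  point_density: 2.0
  canopy_penetration: 0.35
  vertical_noise_sd: 0.05
  band_noise_sd: 0.01
  plot_agb_noise_cv: 0.15
  cover_samples_per_cell: 1500
  seed: 42
preprocessing:
  mode: ptd
  k_neighbors: 10
  sd_multiplier: 3.0
  seed_cell_size: 20.0
  max_angle_deg: 8.0
  max_distance: 0.5
  dtm_resolution: 2.0
  idw_power: 2.0
  idw_neighbors: 12
metrics:
  canopy_threshold: 2.0
  extinction_k: 0.5
  min_points: 10
  hmax_above_threshold: true
selection:
  correlation_threshold: 0.85
  max_subset_size: 10
  cv_folds: 10
  cv_seed: 0
  smearing_correction: false
sampling:
  n_reference: 700
  biophysical_mode: proxy
  biophysical_noise_sd: 0.05
seed: 42
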