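# Demo analysis on synthetic data with a known posterior-anterior gradient.
# Thresholds follow the analysis defaults: voxel ANOVA FDR q<0.01, Gaussian
# fit gate r2>0.7, 1000 permutation shuffles, FDR q<0.05 across regions.
seed: 11
alpha_voxel: 0.01
r2_gate: 0.7
n_perm: 1000
cluster_min: 5
connectivity: 6
q_regions: 0.05
subject_alpha: 0.05
intensity_threshold: 50.0
era_volumes: 10
run_subject_level: true
synthetic:
  n_subjects: 6
  rating_subjects: 19
  n_runs: 2
  blocks_per_run: 24
  tr: 2.5
  grid_shape: [12, 30, 12]
  voxel_size_mm: 3.0
  axis: 1                      # posterior -> anterior = increasing Y
  gradient_region: [[2, 7], [3, 27], [3, 9]]
  control_region: [[8, 12], [3, 27], [3, 9]]
  amplitude: 1.0               # percent signal change
  width: 1.0                   # scale units
  jitter_sd: 0.3               # scale units of tuning-center jitter
  subject_slope_sd: 0.005      # scale/mm across subjects
  ar: [0.3, 0.2]
  innovation_sd: 0.5
  drift_amplitude: 0.3
  drift_period_s: 128.0
  baseline: 100.0
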