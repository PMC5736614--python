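seed: 0
profile:
  peak_age: 20.5
  peak_logit_positive: 3.2
  peak_logit_negative: 2.9
  curvature_positive: 0.007
  curvature_negative: 0.007
  p_elim_memory: 0.5
  p_too_late: 0.02
  subject_logit_sd: 0.35
  valid_age_range:
  - 8.0
  - 29.0
cohort:
  n_subjects: 271
  age_range_tp1:
  - 8.0
  - 25.0
  n_waves: 3
  wave_gap: 2.0
  retention_per_wave: 0.86
  rois:
  - dorsal_caudate
  - ventral_caudate
  - nucleus_accumbens
  contrasts:
  - informative_value
  - valence
  age_center: 18.5
  random_intercept_sd: 1.0
  residual_sd: 1.0
  inter_roi_corr: 0.66
  performance_coef:
    b0: 94.84
    b1: 0.16
    b2: -0.04
  performance_intercept_sd: 4.0
  performance_residual_sd: 3.0
  coupling: null
  ceiling_rate:
    1: 0.02
    2: 0.05
    3: 0.15
  seed: 0
n_behavioral_subjects: 24
selection_rule: forward_stop
mc_k: 6
mc_r_bar: 0.66
mc_alpha: 0.05
lagged_pairs:
- - 1
  - 2
- - 2
  - 3
peak_bootstrap: 1000
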