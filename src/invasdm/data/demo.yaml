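# Bundled demo: a small two-region synthetic landscape run end to end.
seed: 42
landscape:
  n_rows: 60
  n_cols: 60
  cell_size_m: 1000.0
  n_predictors: 6
  smoothness: 3.0
  correlated_pair: [L1, L2]
  pair_correlation: 0.85
  na_fraction: 0.02
  invasive_region: invasive
  native_region: native
  invasive_fraction: 0.65
truth:
  coefficients:
    L1: 2.0
    L3: -1.0
  intercept: -0.5
sampling:
  n_invasive: 800
  n_native: 120
  n_effort_observations: 20000
  effort_concentration: 1.5
  # the demo landscape is ~60 km across, so the heavy CU tail is scaled to
  # 5 km to leave the native range an eligible background pool
  native_cu_tail_max_m: 5000.0
cu:
  max_cu_m:
    invasive: 1000.0
    native: 15000.0
  keep_missing: false
pa:
  n_sets: 3
  mode:
    invasive: cell
    native: buffer
cv:
  train_frac: 0.7
  n_reps: 2
algorithms: [rf, cta]
hyperparams:
  rf:
    n_estimators: 200
ensemble_schemes: [EMmean, EMca, EMwmean]
metrics:
  boyce_window: 0.1
  boyce_windows: 101
importance:
  n_shuffles: 9
overlap:
  species:
    focal_a: 40
    focal_b: 12
  n_survey_points: 150
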