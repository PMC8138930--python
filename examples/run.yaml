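# Full-chain example: simulate a drift cohort, preprocess, build kinematics
# features, and cross-validate the classifier comparison.
seed: 7
simulate:
  n_positive: 30
  n_negative: 60
  length_range: [30, 120]
  drift_hours: 12
  missing_rate: 0.10
  error_rate: 0.01
preprocess:
  min_rows: 36
  window: 48
  smooth_width: 3
evaluate:
  models: [lstm, cnn, linear_nn, logistic_regression, decision_tree]
  hbs: 6
  k: 5
  hyperparameters:
    lstm: {epochs: 100, patience: 100}
    cnn: {epochs: 100, patience: 100}
    linear_nn: {epochs: 100, patience: 100}
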