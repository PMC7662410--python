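seed: 11
synthetic:
  mode: signals
  n_subjects: 12
  fs_hz: 250
  p_recall: 0.5
  # optional per-emotion shifts applied during simulation, e.g.
  # emotion_shifts:
  #   anger: {mean_rr_ms: -40, scr_rate: 1.5}
schedule: default
model: default
scoring: default
analysis:
  scheme: path
  tol: 1.0e-7
  max_iter: 300
  n_boot: 200
  n_perm: 199
  alpha: 0.05
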