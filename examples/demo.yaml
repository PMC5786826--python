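seed: 7
conditions: [Wimpy, DesMe, Rest, Flash]
simulation:
  n_subjects: 12
  duration_s: 60.0
  conditions: [Wimpy, DesMe, Rest, Flash]
preprocess:
  fs_target: 125.0
  hp_hz: 1.0
  notch: [59.0, 61.0]
  butter_order: 4
rpca:
  enabled: true
  tol: 1.0e-7
  max_iter: 500
corrca:
  n_components: 3
  rank_tol: 1.0e-9
fit_groups: [all, age, sex, age_sex]
ssvep:
  electrodes: [O1, O2, O3, O4, O5]
  f0: 25.0
  bw: 0.5
  n_trials: 128
stats:
  fdr_q: 0.05
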