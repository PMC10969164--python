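scenario:
  n_reference: 36
  n_study: 41
  true_alpha: 56.0
  true_beta: 0.4
  true_sigma: 1.5
  sd_onset: 9.0
  shifts: [-8.0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0,
           0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0]
  study_case_counts: [30, 30, 30, 30, 30, 30, 30, 30, 30, 30, 30, 30, 30, 30,
                      30, 30, 30, 30, 30, 30, 30, 30, 30, 30, 30, 30, 30, 30,
                      30, 30, 30, 30, 30, 30, 30, 30, 30, 30, 30, 30, 30]
  seed: 3
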