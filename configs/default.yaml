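# Default synthetic-cohort configuration (mirrors the built-in defaults).
# task fields mirror TaskConfig; observer blocks mirror ObserverParams.
task:
  base_frequencies_hz: [500.0, 750.0, 1000.0, 1500.0]
  block_diff_percent: [3.0, 2.0, 1.0]
  trials_per_block: 40
  same_fraction: 0.5
  tone_duration_ms: 100.0
  inter_tone_interval_ms: 1000.0
  inter_trial_interval_ms: 500.0

groups:
  - name: ASD
    n_subjects: 21
    observer:
      lambda_contraction: 0.001   # weak contraction
      sigma_encoding: 0.007
      gamma_lapse: 0.02
      rt_model: [lognormal, 6.84, 0.25]
  - name: LAD
    n_subjects: 21
    observer:
      lambda_contraction: 0.006   # strong contraction, like TD
      sigma_encoding: 0.007
      gamma_lapse: 0.02
      rt_model: [lognormal, 6.84, 0.25]
  - name: TD
    n_subjects: 18
    observer:
      lambda_contraction: 0.006
      sigma_encoding: 0.007
      gamma_lapse: 0.02
      rt_model: [lognormal, 6.80, 0.25]

seed: 1
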