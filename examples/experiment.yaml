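# End-to-end WT-vs-KO experiment: cohorts -> averages -> fits -> contrast.
seed: 1
protocol:
  n_pulses: 30
  frequency_hz: 50.0
  current_ma: 0.4
  onset_s: 1.0
recording:
  duration_s: 12.0
  sample_rate_hz: 10.0
  dt_s: 0.001
cohorts:
  wt:
    parameters: {vm: 7.4, dap: 0.67, free: [vm, dap]}
    n_animals: 4
    between_animal_cv: 0.1
    noise_sd_um: 0.05
  ko:
    parameters: {vm: 2.0, dap: 0.31, free: [vm, dap]}
    n_animals: 5
    between_animal_cv: 0.1
    noise_sd_um: 0.05
fitting:
  free: [vm, dap]
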