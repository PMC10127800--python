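# Synthetic wild-type cohort for the `generate` subcommand.
protocol:
  n_pulses: 30
  frequency_hz: 50.0
  current_ma: 0.4
  onset_s: 1.0
parameters:
  vm: 7.4
  dap: 0.67
  free: [vm, dap]
cohort:
  genotype: wt
  n_animals: 4
  between_animal_cv: 0.1
  noise_sd_um: 0.05
  sample_rate_hz: 10.0
  duration_s: 12.0
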