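# Wild-type parameter set under the standard burst protocol.
protocol:
  n_pulses: 30
  frequency_hz: 50.0
  current_ma: 0.4
  onset_s: 1.0
parameters:
  vm: 7.4
  dap: 0.67
  free: [vm, dap]
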