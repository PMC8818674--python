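time_unit: ms
samples:
  leaf_a:
    treatment: control
    timepoint_days: 15
    replicate: 1
  leaf_b:
    treatment: NaCl300
    timepoint_days: 15
    replicate: 1
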