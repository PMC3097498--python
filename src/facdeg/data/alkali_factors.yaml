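# Stress factors for the microwave-assisted alkali degradation design.
- name: naoh
  low: 0.1
  high: 1.0
  units: N
- name: time
  low: 15.0
  high: 30.0
  units: min
- name: power
  low: 420.0
  high: 700.0
  units: W
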