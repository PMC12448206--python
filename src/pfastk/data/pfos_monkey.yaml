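physiological:
  BW: 5.0
  QCC: 19.8
  QfilC: 0.15
  VfilC: 4.0e-4
chemical:
  bioAv: 0.9
  VCC: 0.24
  Tmc: 2.5
  Kt: 0.004
  Free: 4.5e-3
  k12: 3.3
  k21: 3.4
  ka: 132.0
meta:
  chemical: PFOS
  species: cynomolgus monkey
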