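physiological:
  BW: 4.1
  QCC: 19.8
  QfilC: 0.15
  VfilC: 4.0e-4
chemical:
  bioAv: 0.9
  VCC: 0.23
  Tmc: 0.15
  Kt: 0.008
  Free: 1.2e-3
  k12: 3.3
  k21: 3.4
  ka: 230.0
meta:
  chemical: PFOA
  species: cynomolgus monkey
  note: animal refit with bioavailability fixed at 0.9; basis for human scaling
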