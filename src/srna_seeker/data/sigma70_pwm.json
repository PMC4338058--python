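{
 "alphabet": "ACGT",
 "comment": "log2 odds vs uniform background; sigma-70 consensus with 0.85 consensus-base probability",
 "minus35": [
  [
   -2.321928,
   -2.321928,
   -2.321928,
   1.765535,
   -2.321928,
   1.765535
  ],
  [
   -2.321928,
   -2.321928,
   -2.321928,
   -2.321928,
   1.765535,
   -2.321928
  ],
  [
   -2.321928,
   -2.321928,
   1.765535,
   -2.321928,
   -2.321928,
   -2.321928
  ],
  [
   1.765535,
   1.765535,
   -2.321928,
   -2.321928,
   -2.321928,
   -2.321928
  ]
 ],
 "minus10": [
  [
   -2.321928,
   1.765535,
   -2.321928,
   1.765535,
   1.765535,
   -2.321928
  ],
  [
   -2.321928,
   -2.321928,
   -2.321928,
   -2.321928,
   -2.321928,
   -2.321928
  ],
  [
   -2.321928,
   -2.321928,
   -2.321928,
   -2.321928,
   -2.321928,
   -2.321928
  ],
  [
   1.765535,
   -2.321928,
   1.765535,
   -2.321928,
   -2.321928,
   1.765535
  ]
 ]
}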