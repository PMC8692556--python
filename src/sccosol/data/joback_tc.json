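{
 "method_id": "joback_tc",
 "formula_id": "joback_tc",
 "contributions": {
  "-CH3": 0.0141,
  ">CH2": 0.0189,
  ">CH-": 0.0164,
  ">C<": 0.0067,
  "=CH2": 0.0113,
  "=CH-": 0.0129,
  "=CH- (ring)": 0.0082,
  "=C< (ring)": 0.0143,
  "-OH": 0.0741,
  "-O-": 0.0168,
  ">C=O": 0.0380,
  "-COOH": 0.0791,
  "-Cl": 0.0105,
  "-NH2": 0.0243,
  ">NH": 0.0295,
  ">N-": 0.0169
 }
}
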