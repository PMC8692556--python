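{
 "method_id": "joback_tb",
 "formula_id": "joback_tb",
 "contributions": {
  "-CH3": 23.58,
  ">CH2": 22.88,
  ">CH-": 21.74,
  ">C<": 18.25,
  "=CH2": 18.18,
  "=CH-": 24.96,
  "=CH- (ring)": 26.73,
  "=C< (ring)": 31.01,
  "-OH": 92.88,
  "-O-": 22.42,
  ">C=O": 76.75,
  "-COOH": 169.09,
  "-Cl": 38.13,
  "-NH2": 73.23,
  ">NH": 50.17,
  ">N-": 11.74
 }
}
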