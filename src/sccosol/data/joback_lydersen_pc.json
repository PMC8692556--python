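{
 "method_id": "joback_lydersen_pc",
 "formula_id": "joback_pc",
 "contributions": {
  "-CH3": -0.0012,
  ">CH2": 0.0,
  ">CH-": 0.0020,
  ">C<": 0.0043,
  "=CH2": -0.0028,
  "=CH-": -0.0006,
  "=CH- (ring)": 0.0011,
  "=C< (ring)": 0.0008,
  "-OH": 0.0112,
  "-O-": 0.0015,
  ">C=O": 0.0031,
  "-COOH": 0.0077,
  "-Cl": -0.0049,
  "-NH2": 0.0109,
  ">NH": 0.0077,
  ">N-": 0.0074
 }
}
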