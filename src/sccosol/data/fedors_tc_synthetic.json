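{
 "method_id": "fedors_tc",
 "formula_id": "fedors_log_tc",
 "comment": "SYNTHETIC starter table: illustrative increments for exercising the Tc = 535*log10(sum) evaluator, not the published coefficient set. Replace with values from the original source before production use.",
 "contributions": {
  "-CH3": 1.22,
  ">CH2": 1.18,
  ">CH-": 1.00,
  ">C<": 0.80,
  "=CH- (ring)": 1.10,
  "=C< (ring)": 1.20,
  "-OH": 3.10,
  "-O-": 1.30,
  ">C=O": 2.50,
  "-COOH": 4.60,
  "-Cl": 1.80,
  "-NH2": 2.30,
  ">NH": 2.00,
  ">N-": 1.60
 }
}
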