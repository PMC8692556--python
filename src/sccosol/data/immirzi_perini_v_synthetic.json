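{
 "method_id": "immirzi_perini_v",
 "formula_id": "sum_A3_to_cm3",
 "comment": "SYNTHETIC starter table: illustrative crystal-volume increments (angstrom^3 per group) for exercising the V = 0.6022*sum evaluator, not the published coefficient set. Replace with values from the original source before production use.",
 "contributions": {
  "C": 13.9,
  "H": 5.7,
  "N": 11.8,
  "O": 11.4,
  "Cl": 19.9,
  "aromatic CH": 21.0,
  "aromatic C": 15.3
 }
}
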