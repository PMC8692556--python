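{
 "t_dependent": {
  "308": {"kij": 0.58814, "lij": 0.5856, "aard_percent": 3.99},
  "318": {"kij": 0.55098, "lij": 0.52813, "aard_percent": 2.5572},
  "328": {"kij": 0.55315, "lij": 0.52218, "aard_percent": 7.5542},
  "338": {"kij": 0.53741, "lij": 0.48034, "aard_percent": 13.067}
 },
 "t_independent": {
  "kij": 0.79788,
  "lij": 0.74029,
  "beta_over_R": 0.27409,
  "gamma_over_R": -221.54,
  "dsubdelta_over_R": 11.305,
  "aard_percent": 8.2458
 }
}
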