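{
 "name": "carbon dioxide",
 "M_g_mol": 44.01,
 "Tc_K": 304.18,
 "Pc_MPa": 7.38,
 "omega": 0.225
}
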