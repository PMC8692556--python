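{
 "name": "clemastine fumarate",
 "M_g_mol": 459.96,
 "Tc_K": 901.25,
 "Pc_MPa": 1.409,
 "omega": 0.337,
 "Vsolid_m3_mol": 3.64764e-4,
 "psub_Pa": {"308": 0.0114, "318": 0.02699, "328": 0.0603, "338": 0.1277}
}
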