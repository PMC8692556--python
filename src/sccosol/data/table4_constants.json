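{
 "alwi_garlapati": {"values": [1.8759, -18.105, 2.0667], "aard_percent": 14.00, "r2": 0.809},
 "bartle": {"values": [14.719, -7179.9, 6.6739e-3], "aard_percent": 20.2, "r2": 0.765},
 "bian": {"values": [-4.9614, 5.5723e-3, 2030.5, -9.9873, 9.6915], "aard_percent": 11.2, "r2": 0.927},
 "chrastil": {"values": [3.0938, -11.003, -4907.2], "aard_percent": 16.7, "r2": 0.785},
 "ref_chrastil": {"values": [3.0813, -21.619, -4216.6], "aard_percent": 16.7, "r2": 0.784},
 "garlapati_madras": {"values": [-755.12, 859.01, 0.9875, -8597.4, -10.722], "aard_percent": 14.6, "r2": 0.818},
 "mt": {"values": [-8479.4, 1.9629, 14.617], "aard_percent": 21.69, "r2": 0.706},
 "sodeifian": {"values": [-42.487, -6.9315e-4, 2.4265, -4.2127e-4, 1.929e-2, 62.052], "aard_percent": 8.78, "r2": 0.929},
 "reddy_garlapati": {"values": [8.334e-7, 1.3157e-5, -3.3583e-7, 5.6805e-7, -1.3913e-5, 7.7736e-7], "aard_percent": 7.57, "r2": 0.951},
 "mahesh_garlapati": {"values": [-14.614, -2.4145, 3.3127], "aard_percent": 17.9, "r2": 0.797}
}
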