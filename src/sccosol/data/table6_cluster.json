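{
 "new": {"kappa": 0.10756, "a_dp": 443590.0, "b_dp": 1357.1, "c_dp": -9115.7, "aard_percent": 10.3, "r2": 0.936},
 "chen": {"kappa": 0.10794, "a_prime": 6093.7, "b_prime": -70.319, "aard_percent": 12.1, "r2": 0.913}
}
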