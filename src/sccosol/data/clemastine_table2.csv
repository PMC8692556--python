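T_K,P_MPa,rho_kg_m3,y2,S_g_L,sd_y2
308,12,769,1.61e-06,0.0130,5e-08
308,15,817,2.02e-06,0.0173,1.0e-07
308,18,849,2.47e-06,0.0219,1.0e-07
308,21,875,2.84e-06,0.0260,8e-08
308,24,896,3.84e-06,0.0360,2e-08
308,27,914,5.1e-06,0.0488,1.0e-07
318,12,661,2.48e-06,0.0171,6e-08
318,15,744,3.95e-06,0.0307,5e-08
318,18,791,4.31e-06,0.0357,2.0e-07
318,21,824,5.13e-06,0.0442,2.0e-07
318,24,851,5.99e-06,0.0532,9e-08
318,27,872,6.97e-06,0.0636,2.0e-07
328,12,509,2.82e-06,0.0150,1.0e-07
328,15,656,4.14e-06,0.0284,8e-08
328,18,725,4.71e-06,0.0357,2.0e-07
328,21,769,5.58e-06,0.0449,1.0e-07
328,24,802,7.78e-06,0.0652,3.0e-07
328,27,829,8.86e-06,0.0767,4.0e-07
338,12,388,3.59e-06,0.0145,1.0e-07
338,15,557,4.6e-06,0.0268,2.0e-07
338,18,652,5.15e-06,0.0351,7e-08
338,21,710,5.93e-06,0.0440,1.0e-07
338,24,751,8.6e-06,0.0676,4.0e-07
338,27,783,9.41e-06,0.0771,3.0e-07
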