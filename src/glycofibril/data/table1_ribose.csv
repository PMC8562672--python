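t_days,d_M,d_M_err,d_E,d_E_err,delta_rho,delta_rho_err,sugar,concentration
0,65.5,0.1,1.514,0.007,0.055,0.001,ribose,40
3,65.4,0.1,1.547,0.005,0.057,0.001,ribose,40
14,65.0,0.1,1.563,0.005,0.057,0.001,ribose,40
30,64.9,0.1,1.638,0.006,0.060,0.001,ribose,40
90,64.4,0.1,1.695,0.012,0.067,0.001,ribose,40
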