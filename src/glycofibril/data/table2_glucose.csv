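t_days,d_M,d_M_err,d_E,d_E_err,delta_rho,delta_rho_err,sugar,concentration
0,65.5,0.1,1.513,0.006,0.054,0.001,glucose,40
3,65.4,0.1,1.522,0.003,0.052,0.001,glucose,40
14,65.4,0.1,1.524,0.005,0.055,0.001,glucose,40
30,65.5,0.1,1.5325,0.004,0.054,0.001,glucose,40
90,65.4,0.1,1.543,0.006,0.056,0.001,glucose,40
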