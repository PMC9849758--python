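compound,enzyme,K1_uM,K1_sd,KIstar_uM,KIstar_sd,status
32b,trypsin3,,,,,not_determined
32b,beta_tryptase,,,,,not_determined
32b,thrombin,22.6,5,0.45,0.03,ok
45b,trypsin3,,,,,not_determined
45b,beta_tryptase,,,,,not_determined
45b,thrombin,9.97,1.0,1.14,0.11,ok
33b,trypsin3,,,,,not_determined
33b,beta_tryptase,,,,,not_determined
33b,thrombin,4.13,0.7,0.28,0.04,ok
46b,trypsin3,,,,,not_determined
46b,beta_tryptase,,,,,not_determined
46b,thrombin,0.95,0.2,0.07,0.009,ok
34b,trypsin3,0.029,0.005,0.003,0.0003,ok
34b,beta_tryptase,15.8,5,1.11,0.09,ok
34b,thrombin,134,26,4.93,0.51,ok
50b,trypsin3,0.098,0.022,0.003,0.0002,ok
50b,beta_tryptase,3.28,0.5,0.41,0.03,ok
50b,thrombin,,,1.55,0.25,K1_not_fittable
35b,trypsin3,0.001,0.0001,0.0001,0.00001,ok
35b,beta_tryptase,3.20,1.8,0.12,0.01,ok
35b,thrombin,32.7,4,0.63,0.04,ok
52b,trypsin3,0.017,0.0005,0.001,0.00007,ok
52b,beta_tryptase,0.68,0.07,0.06,0.003,ok
52b,thrombin,,,0.62,0.08,K1_not_fittable
36b,trypsin3,0.008,0.0008,0.001,0.0001,ok
36b,beta_tryptase,0.34,0.07,0.09,0.01,ok
36b,thrombin,9.03,0.5,0.03,0.002,ok
54b,trypsin3,0.006,0.0005,0.0008,0.00003,ok
54b,beta_tryptase,0.13,0.03,0.02,0.001,ok
54b,thrombin,,,0.06,0.006,K1_not_fittable
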