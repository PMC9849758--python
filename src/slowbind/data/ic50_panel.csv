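compound,enzyme,ic50_uM,ic50_sd,censor
42,trypsin3,,,gt10
42,beta_tryptase,,,gt10
42,thrombin,,,gt10
42,upa,,,gt10
42,catg,3.23,0.29,value
42,chymotrypsin,2.07,0.85,value
42,ne,,,gt10
44,trypsin3,,,gt10
44,beta_tryptase,,,gt10
44,thrombin,,,gt10
44,upa,,,gt10
44,catg,,,gt10
44,chymotrypsin,,,gt10
44,ne,4.70,0.20,value
45b,trypsin3,0.22,0.02,value
45b,beta_tryptase,0.80,0.05,value
45b,thrombin,0.61,0.17,value
45b,upa,,,gt10
45b,catg,,,gt10
45b,chymotrypsin,,,gt10
45b,ne,,,nd
46b,trypsin3,0.07,0.002,value
46b,beta_tryptase,0.04,0.006,value
46b,thrombin,0.04,0.006,value
46b,upa,0.42,0.05,value
46b,catg,,,gt10
46b,chymotrypsin,,,gt10
46b,ne,,,nd
47b,trypsin3,0.52,0.24,value
47b,beta_tryptase,2.49,0.19,value
47b,thrombin,3.55,0.17,value
47b,upa,4.62,0.17,value
47b,catg,,,gt10
47b,chymotrypsin,,,gt10
47b,ne,,,gt10
49b,trypsin3,0.09,0.005,value
49b,beta_tryptase,1.11,0.05,value
49b,thrombin,1.18,0.04,value
49b,upa,6.75,0.52,value
49b,catg,4.47,0.51,value
49b,chymotrypsin,,,gt10
49b,ne,,,gt10
50b,trypsin3,0.03,0.01,value
50b,beta_tryptase,0.36,0.07,value
50b,thrombin,3.52,0.39,value
50b,upa,0.02,0.0001,value
50b,catg,0.36,0.004,value
50b,chymotrypsin,1.64,0.50,value
50b,ne,,,gt10
52b,trypsin3,0.01,0.001,value
52b,beta_tryptase,0.07,0.003,value
52b,thrombin,0.76,0.02,value
52b,upa,0.01,0.003,value
52b,catg,0.05,0.007,value
52b,chymotrypsin,,,gt10
52b,ne,,,gt10
54b,trypsin3,0.008,0.002,value
54b,beta_tryptase,0.11,0.009,value
54b,thrombin,0.20,0.02,value
54b,upa,0.006,0.0001,value
54b,catg,0.12,0.01,value
54b,chymotrypsin,5.60,1.06,value
54b,ne,,,gt10
55b,trypsin3,0.24,0.01,value
55b,beta_tryptase,0.37,0.09,value
55b,thrombin,,,gt10
55b,upa,2.22,0.07,value
55b,catg,1.62,0.09,value
55b,chymotrypsin,,,gt10
55b,ne,,,nd
56b,trypsin3,0.22,0.004,value
56b,beta_tryptase,0.39,0.10,value
56b,thrombin,,,gt10
56b,upa,5.19,0.08,value
56b,catg,0.62,0.009,value
56b,chymotrypsin,,,gt10
56b,ne,,,nd
57b,trypsin3,0.18,0.07,value
57b,beta_tryptase,0.02,0.0002,value
57b,thrombin,,,gt10
57b,upa,0.16,0.04,value
57b,catg,0.12,0.04,value
57b,chymotrypsin,,,gt10
57b,ne,,,nd
58b,trypsin3,0.16,0.004,value
58b,beta_tryptase,6.41,0.15,value
58b,thrombin,0.16,0.004,value
58b,upa,6.51,1.15,value
58b,catg,2.90,0.15,value
58b,chymotrypsin,,,gt10
58b,ne,,,nd
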