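compound,tag,benzyl_guanidine,enzyme,kapp,kapp_sd,mechanism,status
32b,alkyne,false,trypsin3,1800,66,irreversible,ok
32b,alkyne,false,beta_tryptase,41,5,irreversible,ok
32b,alkyne,false,thrombin,64,8,reversible_slow_binding,ok
32b,alkyne,false,upa,41,4,irreversible,ok
32b,alkyne,false,catg,,,reversible_slow_binding,curve_fit_impossible
45b,desthiobiotin,false,trypsin3,1700,122,irreversible,ok
45b,desthiobiotin,false,beta_tryptase,237,42,irreversible,ok
45b,desthiobiotin,false,thrombin,19,2,reversible_slow_binding,ok
45b,desthiobiotin,false,upa,,,,not_determined
45b,desthiobiotin,false,catg,,,,not_determined
33b,alkyne,false,trypsin3,3500,40,irreversible,ok
33b,alkyne,false,beta_tryptase,2800,82,irreversible,ok
33b,alkyne,false,thrombin,1100,42,reversible_slow_binding,ok
33b,alkyne,false,upa,1500,12,irreversible,ok
33b,alkyne,false,catg,,,reversible_slow_binding,curve_fit_impossible
46b,desthiobiotin,false,trypsin3,9200,349,irreversible,ok
46b,desthiobiotin,false,beta_tryptase,7500,1475,irreversible,ok
46b,desthiobiotin,false,thrombin,6300,290,reversible_slow_binding,ok
46b,desthiobiotin,false,upa,940,37,irreversible,ok
46b,desthiobiotin,false,catg,,,,not_determined
34b,alkyne,true,trypsin3,40000,2642,reversible_slow_binding,ok
34b,alkyne,true,beta_tryptase,712,41,reversible_slow_binding,ok
34b,alkyne,true,thrombin,17,1,reversible_slow_binding,ok
34b,alkyne,true,upa,7500,725,irreversible,ok
34b,alkyne,true,catg,,,reversible_slow_binding,curve_fit_impossible
50b,desthiobiotin,true,trypsin3,49000,2979,reversible_slow_binding,ok
50b,desthiobiotin,true,beta_tryptase,3200,613,reversible_slow_binding,ok
50b,desthiobiotin,true,thrombin,47,5,reversible_slow_binding,ok
50b,desthiobiotin,true,upa,33000,12000,irreversible,ok
50b,desthiobiotin,true,catg,,,reversible_slow_binding,curve_fit_impossible
35b,alkyne,true,trypsin3,,,reversible_slow_binding,curve_fit_impossible
35b,alkyne,true,beta_tryptase,7000,582,reversible_slow_binding,ok
35b,alkyne,true,thrombin,128,5,reversible_slow_binding,ok
35b,alkyne,true,upa,130000,30000,irreversible,ok
35b,alkyne,true,catg,477,67,reversible_slow_binding,ok
52b,desthiobiotin,true,trypsin3,86000,8250,reversible_slow_binding,ok
52b,desthiobiotin,true,beta_tryptase,18000,1184,reversible_slow_binding,ok
52b,desthiobiotin,true,thrombin,49,5,reversible_slow_binding,ok
52b,desthiobiotin,true,upa,38000,4175,irreversible,ok
52b,desthiobiotin,true,catg,,,reversible_slow_binding,curve_fit_impossible
36b,alkyne,true,trypsin3,29000,6499,reversible_slow_binding,ok
36b,alkyne,true,beta_tryptase,61000,6860,reversible_slow_binding,ok
36b,alkyne,true,thrombin,251,16,reversible_slow_binding,ok
36b,alkyne,true,upa,320000,29000,irreversible,ok
36b,alkyne,true,catg,,,reversible_slow_binding,curve_fit_impossible
54b,desthiobiotin,true,trypsin3,,,reversible_slow_binding,curve_fit_impossible
54b,desthiobiotin,true,beta_tryptase,,,reversible_slow_binding,curve_fit_impossible
54b,desthiobiotin,true,thrombin,,,reversible_slow_binding,curve_fit_impossible
54b,desthiobiotin,true,upa,230000,36000,irreversible,ok
54b,desthiobiotin,true,catg,,,reversible_slow_binding,curve_fit_impossible
37b,alkyne,false,trypsin3,293,34,irreversible,ok
37b,alkyne,false,beta_tryptase,375,34,irreversible,ok
37b,alkyne,false,thrombin,,,,not_determined
37b,alkyne,false,upa,124,23,irreversible,ok
37b,alkyne,false,catg,582,2,irreversible,ok
55b,desthiobiotin,false,trypsin3,231,18,irreversible,ok
55b,desthiobiotin,false,beta_tryptase,347,19,irreversible,ok
55b,desthiobiotin,false,thrombin,,,,not_determined
55b,desthiobiotin,false,upa,77,1,irreversible,ok
55b,desthiobiotin,false,catg,301,85,irreversible,ok
38b,alkyne,false,trypsin3,358,6,irreversible,ok
38b,alkyne,false,beta_tryptase,2000,54,irreversible,ok
38b,alkyne,false,thrombin,,,,not_determined
38b,alkyne,false,upa,215,7,irreversible,ok
38b,alkyne,false,catg,1400,52,irreversible,ok
56b,desthiobiotin,false,trypsin3,334,85,irreversible,ok
56b,desthiobiotin,false,beta_tryptase,321,2,irreversible,ok
56b,desthiobiotin,false,thrombin,,,,not_determined
56b,desthiobiotin,false,upa,62,2,irreversible,ok
56b,desthiobiotin,false,catg,420,37,irreversible,ok
39b,alkyne,false,trypsin3,1100,164,irreversible,ok
39b,alkyne,false,beta_tryptase,4500,547,irreversible,ok
39b,alkyne,false,thrombin,,,,not_determined
39b,alkyne,false,upa,2500,86,irreversible,ok
39b,alkyne,false,catg,2300,347,reversible_slow_binding,ok
57b,desthiobiotin,false,trypsin3,1300,340,irreversible,ok
57b,desthiobiotin,false,beta_tryptase,6500,1203,irreversible,ok
57b,desthiobiotin,false,thrombin,,,,not_determined
57b,desthiobiotin,false,upa,2500,11,irreversible,ok
57b,desthiobiotin,false,catg,1100,117,reversible_slow_binding,ok
41b,alkyne,false,trypsin3,1700,142,irreversible,ok
41b,alkyne,false,beta_tryptase,27,2,irreversible,ok
41b,alkyne,false,thrombin,4100,38,irreversible,ok
41b,alkyne,false,upa,,,,not_determined
41b,alkyne,false,catg,,,,not_determined
31b,alkyne,false,trypsin3,1300,28,irreversible,ok
31b,alkyne,false,beta_tryptase,136,3,irreversible,ok
31b,alkyne,false,thrombin,1300,5,irreversible,ok
31b,alkyne,false,upa,188,1,irreversible,ok
31b,alkyne,false,catg,,,,not_determined
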