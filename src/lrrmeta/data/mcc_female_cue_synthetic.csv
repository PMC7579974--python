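study_id,n_t,mean_t,sd_t,n_c,mean_c,sd_c
Study_01,33,3.082,1.146,33,3.270,0.975
Study_02,256,4.662,1.072,256,4.681,1.919
Study_03,150,5.514,1.118,150,6.116,2.052
Study_04,262,2.790,0.872,262,3.181,0.751
Study_05,154,5.409,1.281,106,6.020,1.990
Study_06,221,5.356,2.053,221,4.915,1.057
Study_07,166,6.004,1.296,166,6.250,2.191
Study_08,214,2.835,0.859,214,3.144,0.883
Study_09,131,4.960,1.525,155,6.308,1.949
Study_10,124,3.392,1.221,135,3.107,1.269
Study_11,253,6.314,1.551,253,5.717,1.495
Study_12,181,5.106,1.548,181,4.699,0.967
Study_13,208,5.479,1.122,215,5.016,1.580
Study_14,138,5.113,1.868,138,4.581,1.371
Study_15,228,5.429,1.461,228,5.192,1.413
Study_16,73,3.513,1.172,73,3.590,1.209
Study_17,225,3.866,1.111,225,3.837,0.865
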