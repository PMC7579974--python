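study_id,n_t,mean_t,sd_t,n_c,mean_c,sd_c
Trial_01,125,119.1,54.5,125,79.58,30.64
Trial_02,100,84.99,31.77,100,93.09,69.26
Trial_03,67,80.2,50.81,67,38.99,17.07
Trial_04,139,75.61,26.22,139,81.71,35.92
Trial_05,136,89.79,37.95,136,77.87,61.68
Trial_06,125,102.5,51.26,125,82.01,33.53
Trial_07,37,4.207,2.208,37,2.655,0.9012
Trial_08,143,144.7,58.26,143,82.61,26.85
Trial_09,14,125.9,22.06,14,79.5,31.76
Trial_10,23,107.5,63.61,23,46.56,17.46
Trial_11,119,2832,1121,119,1711,923.9
Trial_12,58,100.6,51.88,58,92.86,46.37
Trial_13,45,42.64,48.82,45,45.32,20.47
Trial_14,32,70.45,23.38,32,62.52,38.49
Trial_15,131,45.08,25.99,131,43.58,18.84
Trial_16,117,61.57,32.33,117,59.81,20.92
Trial_17,146,2898,1334,146,1938,896
Trial_18,150,94.04,67.14,150,69.74,41.95
Trial_19,102,86.82,50.6,102,65.95,25.45
Trial_20,146,1.821,1.108,146,1.771,0.7
Trial_21,21,136.9,93.29,21,71.11,32.53
Trial_22,11,119.3,40.76,11,68.92,23.02
Trial_23,137,2659,1169,137,1966,640.7
Trial_24,50,152.7,126.3,50,94.94,36.9
Trial_25,126,75.9,30.01,126,73.17,26.8
Trial_26,11,1937,698.7,11,1782,1083
Trial_27,144,41.73,15.78,144,45.71,16.77
Trial_28,27,1719,578.3,27,1817,1432
Trial_29,134,4.028,2.522,126,2.643,1.599
Trial_30,59,2204,1217,49,1289,708.1
Trial_31,156,82.44,40.89,156,66.05,29.18
Trial_32,41,107.7,57.11,41,81.73,26.56
Trial_33,128,1152,481.3,128,1388,860.6
Trial_34,32,62.19,31.51,32,90.88,50.48
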