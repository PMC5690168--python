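# generated by scripts/generate_xs_tables.py; Cromer-Liberman photoabsorption, IT92 form factors, Waller-Hartree closure S(x,Z)
E_keV,sigma_pe,sigma_incoh,sigma_coh,mu_en_rho
1,2781.3,0.0083247,3.0333,2781.3
1.07978,2277.8,0.0095903,2.9987,2277.8
1.16591,1862.8,0.011036,2.9594,1862.8
1.25893,1522,0.012668,2.9154,1522
1.35936,1242.4,0.014514,2.8659,1242.4
1.4678,1013.3,0.016582,2.811,1013.3
1.58489,825.75,0.018894,2.7502,825.75
1.71133,672.33,0.021459,2.6835,672.33
1.84785,546.95,0.024286,2.6109,546.95
1.99526,444.58,0.027386,2.5324,444.58
2.15443,361.07,0.030742,2.4486,361.07
2.32631,292.99,0.034368,2.3596,292.99
2.51189,237.55,0.03822,2.2666,237.55
2.71227,192.43,0.042308,2.1697,192.43
2.82184,172.55,0.044485,2.1188,172.55
2.82296,1781.8,0.044507,2.1183,1636.8
2.92864,1631.8,0.04656,2.0707,1503.8
3.16228,1339.3,0.050981,1.9699,1242
3.41455,1098,0.055485,1.869,1024.2
3.68695,898.96,0.060063,1.7685,842.96
3.98107,735.11,0.064633,1.6699,692.7
4.29866,600.1,0.069173,1.5737,568.04
4.64159,489.06,0.073627,1.4809,464.86
5,400.45,0.077832,1.3946,382.06
5.01187,397.9,0.077965,1.3919,379.66
5.4117,323.15,0.082174,1.3068,309.43
5.84341,261.88,0.08623,1.2258,251.59
6.30957,211.82,0.090159,1.1485,204.11
6.81292,171.09,0.09396,1.0747,165.32
7.35642,138,0.097675,1.0038,133.69
7.94328,111.16,0.10132,0.93552,107.95
8.57696,89.421,0.10494,0.86931,87.028
9.26119,71.804,0.10853,0.805,70.025
10,57.572,0.11212,0.74249,56.252
10.7978,46.111,0.11569,0.68191,45.133
11.6591,36.893,0.11925,0.62338,36.169
12.5893,29.473,0.12276,0.56734,28.938
13.5936,23.505,0.12622,0.51392,23.112
14.678,18.731,0.12954,0.46375,18.441
15,17.563,0.13046,0.4501,17.298
15.8489,14.914,0.13273,0.41677,14.702
17.1133,11.865,0.1357,0.37356,11.71
18.4785,9.431,0.13847,0.33381,9.3189
19.9526,7.4904,0.14093,0.29787,7.4097
20,7.4371,0.141,0.29681,7.3573
21.5443,5.944,0.14313,0.26525,5.8868
23.2631,4.713,0.14501,0.23603,4.673
25,3.788,0.14653,0.21122,3.7602
25.1189,3.7338,0.14663,0.20966,3.7067
27.1227,2.9547,0.14803,0.18569,2.9373
29.2864,2.3342,0.14923,0.16392,2.3241
30,2.1675,0.14956,0.15756,2.1593
31.6228,1.8428,0.15019,0.14437,1.8382
34.1455,1.454,0.15092,0.12684,1.4537
35,1.347,0.15111,0.12162,1.3478
36.8695,1.1465,0.15141,0.11125,1.1494
39.8107,0.90352,0.15165,0.097404,0.90901
40,0.89029,0.15166,0.096603,0.89593
42.9866,0.71156,0.15165,0.085161,0.71914
46.4159,0.56004,0.15143,0.074343,0.56934
50.1187,0.4405,0.15098,0.064817,0.45127
54.117,0.34626,0.15033,0.056436,0.3583
58.4341,0.27201,0.14946,0.049082,0.28519
63.0957,0.21355,0.14841,0.042635,0.22776
68.1292,0.16755,0.14717,0.036998,0.18272
73.5642,0.13137,0.14577,0.032072,0.14746
79.4328,0.10294,0.14419,0.02778,0.1199
85.7696,0.080609,0.14247,0.024039,0.09841
92.6119,0.063083,0.1406,0.020791,0.081698
100,0.049336,0.1386,0.017966,0.068741
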