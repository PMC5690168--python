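# generated by scripts/generate_xs_tables.py; Cromer-Liberman photoabsorption, IT92 form factors, Waller-Hartree closure S(x,Z)
E_keV,sigma_pe,sigma_incoh,sigma_coh,mu_en_rho
1,2145.1,0.012518,1.0786,2145.1
1.07978,1731.2,0.014392,1.0608,1731.2
1.16591,1394.5,0.016525,1.0408,1394.5
1.25893,1120.8,0.018923,1.0186,1120.8
1.35936,899.79,0.021622,0.99384,899.79
1.4678,721.57,0.024633,0.9666,721.57
1.58489,578.01,0.027976,0.93678,578.01
1.71133,462.49,0.031666,0.90444,462.49
1.84785,369.65,0.035698,0.86971,369.65
1.99526,295.11,0.040088,0.83271,295.11
2.15443,235.35,0.044797,0.79384,235.35
2.32631,187.47,0.049841,0.75325,187.47
2.51189,149.17,0.055139,0.71162,149.17
2.71227,118.56,0.060704,0.66912,118.56
2.92864,94.13,0.066423,0.62657,94.13
3.16228,74.614,0.0723,0.58415,74.615
3.41455,59.075,0.078206,0.54266,59.076
3.68695,46.729,0.084129,0.50225,46.729
3.98107,36.928,0.089952,0.46354,36.929
4.29866,29.156,0.095645,0.42668,29.157
4.64159,22.998,0.10112,0.39198,22.999
5,18.257,0.10619,0.36054,18.259
5.01187,18.123,0.10634,0.35957,18.125
5.4117,14.266,0.11128,0.32948,14.268
5.84341,11.214,0.11588,0.30177,11.215
6.30957,8.8085,0.12016,0.27627,8.8102
6.81292,6.9145,0.1241,0.25296,6.9164
7.35642,5.424,0.12774,0.2316,5.4261
7.94328,4.252,0.13108,0.21208,4.2543
8.57696,3.331,0.13416,0.19417,3.3334
9.26119,2.6047,0.13701,0.17771,2.6074
10,2.0339,0.13966,0.16253,2.0368
10.7978,1.5876,0.14214,0.14846,1.5907
11.6591,1.2388,0.14446,0.13539,1.2422
12.5893,0.96634,0.14666,0.12318,0.97007
13.5936,0.75356,0.14875,0.11177,0.7576
14.678,0.58743,0.15073,0.1011,0.59183
15,0.54746,0.15128,0.098202,0.55195
15.8489,0.45778,0.15262,0.091113,0.46255
17.1133,0.35663,0.15438,0.081824,0.36179
18.4785,0.27774,0.15604,0.073192,0.28332
19.9526,0.21623,0.15755,0.065258,0.22227
20,0.21456,0.1576,0.065023,0.22061
21.5443,0.16828,0.15893,0.057973,0.17481
23.2631,0.13093,0.1601,0.051385,0.13796
25,0.10342,0.16105,0.045769,0.11096
25.1189,0.10183,0.16111,0.045419,0.1094
27.1227,0.079125,0.16188,0.040089,0.087257
29.2864,0.061334,0.16246,0.035314,0.070052
30,0.056626,0.16259,0.033928,0.065532
31.6228,0.047548,0.16281,0.031068,0.056874
34.1455,0.036864,0.16295,0.027285,0.046821
35,0.033964,0.16295,0.02616,0.044129
36.8695,0.028583,0.16288,0.02393,0.039193
39.8107,0.022165,0.1626,0.020954,0.033448
40,0.021819,0.16258,0.020782,0.033145
42.9866,0.017189,0.16212,0.018323,0.029166
46.4159,0.013331,0.16145,0.015998,0.026021
50.1187,0.010341,0.16059,0.01395,0.023759
54.117,0.0080215,0.15955,0.012147,0.022185
58.4341,0.006223,0.15833,0.010564,0.021144
63.0957,0.0048282,0.15694,0.0091768,0.020519
68.1292,0.0037464,0.15539,0.0079637,0.020214
73.5642,0.0029072,0.15369,0.0069035,0.020157
79.4328,0.0022562,0.15184,0.0059806,0.020292
85.7696,0.0017512,0.14985,0.0051759,0.020571
92.6119,0.0013593,0.14774,0.0044788,0.02096
100,0.0010552,0.1455,0.0038718,0.021429
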