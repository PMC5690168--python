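# generated by scripts/generate_xs_tables.py; Cromer-Liberman photoabsorption, IT92 form factors, Waller-Hartree closure S(x,Z)
E_keV,sigma_pe,sigma_incoh,sigma_coh,mu_en_rho
1,0.31216,0.023888,0.35855,0.31223
1.07978,0.24418,0.027543,0.35278,0.24426
1.16591,0.19101,0.03173,0.34622,0.19111
1.25893,0.14941,0.036464,0.33889,0.14953
1.35936,0.11687,0.041842,0.33065,0.11703
1.4678,0.091422,0.047883,0.32153,0.09161
1.58489,0.071513,0.05467,0.31143,0.071744
1.71133,0.055939,0.062229,0.3004,0.056223
1.84785,0.043757,0.070607,0.2884,0.044103
1.99526,0.034228,0.079837,0.27548,0.034649
2.15443,0.026774,0.089902,0.26174,0.027284
2.32631,0.020943,0.10084,0.24724,0.021557
2.51189,0.016383,0.11255,0.23217,0.017118
2.71227,0.012815,0.12505,0.21663,0.013691
2.92864,0.010024,0.13816,0.2009,0.011062
3.16228,0.0078412,0.15189,0.1851,0.0090633
3.41455,0.0061336,0.16597,0.16954,0.0075628
3.68695,0.0047979,0.18036,0.15433,0.0064593
3.98107,0.003753,0.19479,0.13973,0.0056707
4.29866,0.0029357,0.20918,0.12584,0.0051352
4.64159,0.0022964,0.22329,0.11282,0.0048021
5,0.00181,0.23656,0.10108,0.0046358
5.01187,0.0017963,0.23698,0.10072,0.0046328
5.4117,0.0014051,0.25012,0.089594,0.0045964
5.84341,0.0010991,0.26256,0.079455,0.0046682
6.30957,0.00085977,0.27424,0.070263,0.00483
6.81292,0.00067254,0.28502,0.061995,0.0050655
7.35642,0.00052608,0.29495,0.054576,0.0053652
7.94328,0.00041151,0.30393,0.047957,0.0057184
8.57696,0.0003219,0.31203,0.042057,0.006121
9.26119,0.0002518,0.31922,0.036819,0.0065667
10,0.00019696,0.3256,0.032175,0.0070548
10.7978,0.00015407,0.33115,0.02807,0.0075819
11.6591,0.00012052,0.33596,0.024448,0.0081487
12.5893,9.4272e-05,0.34005,0.021261,0.0087536
13.5936,7.3742e-05,0.34347,0.018462,0.009398
14.678,5.7683e-05,0.34625,0.016011,0.010081
15,5.3813e-05,0.34693,0.015375,0.010282
15.8489,4.5121e-05,0.34844,0.013867,0.010806
17.1133,3.5295e-05,0.35009,0.011997,0.011571
18.4785,2.7609e-05,0.35122,0.010369,0.01238
19.9526,2.1596e-05,0.35188,0.0089527,0.013232
20,2.1433e-05,0.3519,0.0089121,0.013259
21.5443,1.6893e-05,0.35211,0.0077238,0.01413
23.2631,1.3214e-05,0.35192,0.0066587,0.015075
25,1.0495e-05,0.3514,0.00579,0.016004
25.1189,1.0337e-05,0.35135,0.0057368,0.016067
27.1227,8.0857e-06,0.35043,0.0049395,0.017107
29.2864,6.3248e-06,0.34918,0.004251,0.018196
30,5.8559e-06,0.34872,0.004055,0.018547
31.6228,4.9475e-06,0.34761,0.0036567,0.019333
34.1455,3.87e-06,0.34574,0.0031445,0.020518
35,3.5757e-06,0.34507,0.002995,0.02091
36.8695,3.0273e-06,0.34357,0.002703,0.02175
39.8107,2.368e-06,0.34113,0.002323,0.023026
40,2.3323e-06,0.34097,0.0023014,0.023107
42.9866,1.8523e-06,0.33842,0.0019959,0.024347
46.4159,1.4489e-06,0.33545,0.0017148,0.025707
50.1187,1.1334e-06,0.33224,0.0014729,0.027106
54.117,8.8658e-07,0.32878,0.0012652,0.028539
58.4341,6.935e-07,0.3251,0.0010867,0.030002
63.0957,5.4248e-07,0.32119,0.00093352,0.03149
68.1292,4.2434e-07,0.31707,0.00080203,0.032998
73.5642,3.3193e-07,0.31274,0.0006892,0.034521
79.4328,2.5965e-07,0.30822,0.00059263,0.036051
85.7696,2.031e-07,0.30351,0.00050965,0.037583
92.6119,1.5887e-07,0.29862,0.00043903,0.03911
100,1.2427e-07,0.29357,0.00037812,0.040624
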