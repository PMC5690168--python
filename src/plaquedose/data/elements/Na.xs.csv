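# generated by scripts/generate_xs_tables.py; Cromer-Liberman photoabsorption, IT92 form factors, Waller-Hartree closure S(x,Z)
E_keV,sigma_pe,sigma_incoh,sigma_coh,mu_en_rho
1,617.85,0.010449,1.9206,617.85
1.07189,512.23,0.011648,1.8996,512.23
1.07231,5771,0.011656,1.8995,5653.6
1.07978,5975.8,0.011781,1.8973,5855.1
1.16591,6374.7,0.013233,1.8719,6255.4
1.25893,5200.2,0.014811,1.8445,5110
1.35936,4244.8,0.016505,1.8153,4176.7
1.4678,3482.8,0.018325,1.7841,3431
1.58489,2859.3,0.020255,1.7512,2819.9
1.71133,2342.7,0.022308,1.7166,2312.9
1.84785,1915.6,0.024474,1.6803,1893
1.99526,1563.3,0.026767,1.6422,1546.2
2.15443,1273.1,0.029195,1.6022,1260.2
2.32631,1034,0.031774,1.5602,1024.3
2.51189,838.45,0.03453,1.5158,831.17
2.71227,678.85,0.03748,1.4689,673.39
2.92864,548.77,0.040659,1.4191,544.68
3.16228,442.61,0.044085,1.3663,439.56
3.41455,356.42,0.04778,1.3104,354.14
3.68695,286.67,0.051762,1.2513,284.97
3.98107,230.29,0.056028,1.1895,229.03
4.29866,184.77,0.060587,1.1251,183.83
4.64159,148.07,0.065409,1.0588,147.37
5,119.22,0.070323,0.99316,118.71
5.01187,118.4,0.070484,0.99104,117.89
5.4117,94.586,0.075758,0.92275,94.205
5.84341,75.487,0.081194,0.85463,75.206
6.30957,60.186,0.086731,0.78754,59.979
6.81292,47.94,0.092295,0.72231,47.788
7.35642,38.148,0.097842,0.65947,38.037
7.94328,30.327,0.10327,0.59983,30.245
8.57696,24.086,0.10856,0.54349,24.026
9.26119,19.094,0.11361,0.49108,19.051
10,15.113,0.11842,0.44239,15.083
10.7978,11.954,0.12289,0.3978,11.932
11.6591,9.448,0.12705,0.35691,9.4336
12.5893,7.4623,0.13083,0.3199,7.4529
13.5936,5.8897,0.13426,0.28629,5.8841
14.678,4.6451,0.13731,0.25606,4.6425
15,4.3431,0.13811,0.24806,4.341
15.8489,3.661,0.14003,0.2288,3.6605
17.1133,2.8833,0.1424,0.20432,2.8845
18.4785,2.2691,0.14448,0.1823,2.2718
19.9526,1.7845,0.14627,0.16251,1.7883
20,1.7713,0.14632,0.16194,1.7752
21.5443,1.4024,0.1478,0.14472,1.4072
23.2631,1.1013,0.14909,0.12874,1.1069
25,0.87724,0.15011,0.11518,0.8836
25.1189,0.86418,0.15017,0.11433,0.87058
27.1227,0.67776,0.15111,0.10112,0.68489
29.2864,0.53126,0.15192,0.08907,0.53909
30,0.49214,0.15214,0.085552,0.50018
31.6228,0.41619,0.15253,0.07827,0.42471
34.1455,0.32585,0.15296,0.068614,0.33506
35,0.30112,0.15304,0.06575,0.31055
36.8695,0.25498,0.15315,0.060081,0.26487
39.8107,0.1994,0.15314,0.052534,0.20998
40,0.19639,0.15313,0.052098,0.20701
42.9866,0.15585,0.15291,0.045897,0.16713
46.4159,0.12174,0.15248,0.040052,0.13373
50.1187,0.095035,0.15184,0.034922,0.10775
54.117,0.074147,0.15102,0.030417,0.087591
58.4341,0.057817,0.15002,0.02647,0.072001
63.0957,0.045056,0.14884,0.023011,0.05999
68.1292,0.035092,0.1475,0.019988,0.050781
73.5642,0.027315,0.146,0.017345,0.043764
79.4328,0.021249,0.14434,0.01504,0.038458
85.7696,0.016521,0.14255,0.013031,0.034489
92.6119,0.012837,0.14063,0.011283,0.031559
100,0.0099685,0.13858,0.0097636,0.029437
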