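# generated by scripts/generate_xs_tables.py; Cromer-Liberman photoabsorption, IT92 form factors, Waller-Hartree closure S(x,Z)
E_keV,sigma_pe,sigma_incoh,sigma_coh,mu_en_rho
1,3280.3,0.0096801,1.2905,3280.3
1.07978,2659.3,0.011146,1.2741,2659.3
1.16591,2152.9,0.01283,1.2553,2152.9
1.25893,1740.5,0.014738,1.2343,1740.5
1.35936,1405.2,0.016912,1.2105,1405.2
1.4678,1133,0.019361,1.184,1133
1.58489,912.23,0.022122,1.1545,912.23
1.71133,732.91,0.025206,1.122,732.91
1.84785,588.07,0.028638,1.0863,588.07
1.99526,471.33,0.03243,1.0476,471.33
2.15443,377.35,0.036583,1.006,377.35
2.32631,301.77,0.04111,0.96164,301.77
2.51189,241.06,0.045973,0.91503,241.06
2.71227,192.34,0.051185,0.86637,192.34
2.92864,153.3,0.056666,0.81649,153.3
3.16228,121.96,0.062421,0.76563,121.97
3.41455,96.907,0.068339,0.71479,96.907
3.68695,76.925,0.074409,0.66423,76.925
3.98107,61.006,0.080516,0.61484,61.007
4.29866,48.336,0.08663,0.56688,48.337
4.64159,38.261,0.092655,0.52095,38.262
5,30.479,0.098361,0.47862,30.48
5.01187,30.258,0.098542,0.4773,30.259
5.4117,23.906,0.10423,0.43618,23.908
5.84341,18.87,0.10966,0.3978,18.872
6.30957,14.881,0.11481,0.36216,14.883
6.81292,11.724,0.11961,0.32939,11.726
7.35642,9.2284,0.12407,0.2993,9.2305
7.94328,7.2563,0.12816,0.27194,7.2585
8.57696,5.7009,0.1319,0.247,5.7034
9.26119,4.4711,0.13529,0.22439,4.4738
10,3.5015,0.13838,0.20382,3.5045
10.7978,2.7411,0.14119,0.18509,2.7443
11.6591,2.1449,0.14376,0.16798,2.1484
12.5893,1.6778,0.14612,0.1523,1.6815
13.5936,1.3118,0.14829,0.13788,1.3159
14.678,1.0252,0.1503,0.12459,1.0296
15,0.95615,0.15084,0.12102,0.96066
15.8489,0.80095,0.15215,0.11233,0.80572
17.1133,0.62548,0.15385,0.10102,0.63064
18.4785,0.48825,0.15542,0.090587,0.49382
19.9526,0.38098,0.15684,0.080998,0.38699
20,0.37806,0.15688,0.080714,0.3841
21.5443,0.29715,0.15812,0.072182,0.30364
23.2631,0.23167,0.15925,0.064139,0.23867
25,0.18336,0.16017,0.057234,0.19085
25.1189,0.18055,0.16022,0.056803,0.18807
27.1227,0.14058,0.161,0.050196,0.14866
29.2864,0.10922,0.16161,0.044242,0.11789
30,0.10091,0.16175,0.042514,0.10976
31.6228,0.084857,0.162,0.038945,0.09413
34.1455,0.065922,0.16218,0.034222,0.075829
35,0.060773,0.1622,0.032819,0.070888
36.8695,0.051209,0.16215,0.030038,0.061771
39.8107,0.039778,0.16193,0.026326,0.051017
40,0.039162,0.1619,0.026111,0.050444
42.9866,0.030897,0.16149,0.023045,0.042833
46.4159,0.023998,0.16087,0.020144,0.036649
50.1187,0.018638,0.16005,0.017586,0.032022
54.117,0.014474,0.15905,0.015333,0.028607
58.4341,0.01124,0.15787,0.013352,0.026134
63.0957,0.0087286,0.15653,0.011613,0.024394
68.1292,0.0067776,0.15501,0.010089,0.023223
73.5642,0.0052625,0.15335,0.0087563,0.022494
79.4328,0.0040858,0.15154,0.0075927,0.022106
85.7696,0.0031721,0.14958,0.0065774,0.021979
92.6119,0.0024626,0.1475,0.0056951,0.022053
100,0.0019116,0.1453,0.0049264,0.022277
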