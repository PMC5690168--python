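# generated by scripts/generate_xs_tables.py; Cromer-Liberman photoabsorption, IT92 form factors, Waller-Hartree closure S(x,Z)
E_keV,sigma_pe,sigma_incoh,sigma_coh,mu_en_rho
1,5833.1,0.0099637,3.6925,5833.1
1.07978,4812.3,0.011317,3.6451,4812.3
1.16591,3964.6,0.012813,3.5929,3964.6
1.25893,3261.6,0.014459,3.5359,3261.6
1.35936,2679.6,0.016254,3.4741,2679.6
1.4678,2198.5,0.018207,3.4076,2198.5
1.58489,1801.4,0.020309,3.3365,1801.4
1.71133,1474.1,0.022571,3.2607,1474.1
1.84785,1204.7,0.024981,3.1808,1204.7
1.99526,982.82,0.02755,3.0964,982.82
2.15443,801.03,0.03027,3.0082,801.03
2.32631,652.15,0.033154,2.9157,652.15
2.51189,530.39,0.036196,2.8195,530.39
2.71227,431,0.039413,2.7192,431
2.92864,349.95,0.042799,2.6152,349.95
3.16228,283.61,0.046369,2.5074,283.61
3.41455,229.59,0.050109,2.3965,229.59
3.68695,185.76,0.05403,2.2826,185.76
3.98107,150.21,0.058104,2.1665,150.21
4.29866,121.39,0.062332,2.0488,121.39
4.64159,98.045,0.066672,1.9306,98.045
4.96541,81.227,0.070563,1.8269,81.227
4.96739,734.1,0.070586,1.8263,605.86
5,720.31,0.070969,1.8162,595.3
5.01187,715.39,0.071108,1.8126,591.53
5.4117,581.2,0.07559,1.6962,488.01
5.84341,476.76,0.080075,1.5823,405.96
6.30957,390.33,0.084518,1.472,336.65
6.81292,318.86,0.088851,1.3665,278.25
7.35642,259.98,0.093054,1.2661,229.32
7.94328,211.61,0.097055,1.1717,188.49
8.57696,171.93,0.10087,1.0831,154.54
9.26119,139.43,0.10445,1.0006,126.37
10,112.88,0.10783,0.92335,103.09
10.7978,91.155,0.11101,0.85132,83.832
11.6591,73.521,0.11403,0.78361,68.052
12.5893,59.23,0.1169,0.71986,55.151
13.5936,47.662,0.11966,0.65954,44.623
14.678,38.308,0.12231,0.60238,36.047
15,36.006,0.12305,0.58675,33.927
15.8489,30.755,0.12487,0.54816,29.075
17.1133,24.661,0.12733,0.49693,23.415
18.4785,19.752,0.1297,0.44857,18.829
19.9526,15.801,0.13193,0.40341,15.119
20,15.692,0.132,0.40206,15.017
21.5443,12.626,0.13404,0.36129,12.123
23.2631,10.074,0.13595,0.32262,9.7039
25,8.1437,0.1376,0.28917,7.8677
25.1189,8.0302,0.1377,0.28708,7.7594
27.1227,6.3931,0.13923,0.25482,6.1958
29.2864,5.0783,0.14056,0.22551,4.9355
30,4.7239,0.14093,0.21696,4.5951
31.6228,4.0314,0.14165,0.19923,3.929
34.1455,3.1983,0.14251,0.17563,3.1259
35,2.9681,0.14273,0.16859,2.9036
36.8695,2.5358,0.14312,0.1546,2.4856
39.8107,2.0092,0.1435,0.13583,1.9756
40,1.9805,0.14352,0.13474,1.9477
42.9866,1.591,0.14365,0.11917,1.5697
46.4159,1.2591,0.14358,0.10437,1.247
50.1187,0.99575,0.14328,0.091278,0.99069
54.117,0.78699,0.14278,0.079702,0.78725
58.4341,0.6216,0.14207,0.069502,0.62596
63.0957,0.49065,0.14118,0.06052,0.49822
68.1292,0.38704,0.1401,0.052635,0.39715
73.5642,0.30511,0.13885,0.04572,0.31728
79.4328,0.24037,0.13743,0.039673,0.25425
85.7696,0.18924,0.13586,0.03439,0.20456
92.6119,0.14889,0.13414,0.029786,0.16546
100,0.11707,0.1323,0.025777,0.13474
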