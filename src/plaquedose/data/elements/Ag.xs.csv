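# generated by scripts/generate_xs_tables.py; Cromer-Liberman photoabsorption, IT92 form factors, Waller-Hartree closure S(x,Z)
E_keV,sigma_pe,sigma_incoh,sigma_coh,mu_en_rho
1,7021.7,0.0047799,7.8325,7021.7
1.07978,5916.3,0.0054954,7.7775,5916.3
1.16591,4974.6,0.0063109,7.715,4974.6
1.25893,4174.4,0.0072295,7.6448,4174.4
1.35936,3496.1,0.0082684,7.5659,3496.1
1.4678,2922.7,0.0094318,7.4779,2922.7
1.58489,2436.5,0.010736,7.3797,2436.5
1.71133,2028.2,0.012188,7.2712,2028.2
1.84785,1686,0.013801,7.1514,1686
1.99526,1399.7,0.015584,7.0201,1399.7
2.15443,1160.4,0.017548,6.8767,1160.4
2.32631,960.51,0.019702,6.7208,960.51
2.51189,793.72,0.022053,6.5526,793.72
2.71227,655.08,0.02461,6.3717,655.08
2.92864,540.05,0.02737,6.1788,540.05
3.16228,444.07,0.030343,5.974,444.07
3.35043,382.83,0.032711,5.8129,382.83
3.35177,1266.4,0.032727,5.8118,1266.4
3.41455,1228.4,0.03351,5.7589,1228.4
3.523,1159.3,0.034856,5.6685,1159.3
3.5244,1578.2,0.034874,5.6673,1578.2
3.68695,1421.9,0.036879,5.5338,1421.9
3.80504,1310.1,0.038315,5.439,1310.1
3.80656,1506.2,0.038333,5.4378,1457.4
3.98107,1345.7,0.040417,5.3013,1304
4.29866,1109.4,0.044122,5.0621,1077.6
4.64159,912.68,0.047955,4.8189,888.44
5,753.93,0.051776,4.581,735.33
5.01187,749.32,0.0519,4.5734,730.89
5.4117,614.12,0.055919,4.3279,600.13
5.84341,502.62,0.059979,4.0844,492.01
6.30957,410.81,0.064049,3.8448,402.78
6.81292,335.3,0.068081,3.6115,329.23
7.35642,273.27,0.072064,3.385,268.69
7.94328,222.45,0.075942,3.1676,219
8.57696,180.9,0.07973,2.9586,178.3
9.26119,146.89,0.083387,2.7594,144.94
10,119.13,0.086946,2.5684,117.67
10.7978,96.56,0.090393,2.3859,95.459
11.6591,78.201,0.093762,2.2106,77.377
12.5893,63.291,0.097054,2.0422,62.674
13.5936,51.193,0.10029,1.8799,50.731
14.678,41.38,0.10346,1.7241,41.036
15,38.957,0.10435,1.6811,38.64
15.8489,33.415,0.10658,1.5746,33.159
17.1133,26.962,0.10959,1.4326,26.771
18.4785,21.742,0.11251,1.2979,21.601
19.9526,17.527,0.11526,1.1722,17.423
20,17.41,0.11535,1.1685,17.308
21.5443,14.123,0.11786,1.0549,14.048
23.2631,11.376,0.12021,0.94772,11.322
25,9.2833,0.12224,0.85483,9.2435
25.1189,9.1597,0.12236,0.84895,9.1208
25.5089,8.7692,0.12277,0.83005,8.733
25.5191,57.235,0.12278,0.82956,21.602
27.1227,48.487,0.12434,0.75766,20.087
29.2864,39.628,0.12616,0.67336,18.134
30,37.187,0.12669,0.64857,17.497
31.6228,32.34,0.12775,0.59692,16.097
34.1455,26.344,0.12912,0.52762,14.093
35,24.65,0.1295,0.50688,13.467
36.8695,21.421,0.13022,0.46557,12.198
39.8107,17.396,0.13108,0.40994,10.462
40,17.173,0.13112,0.40671,10.36
42.9866,14.109,0.13167,0.36042,8.9036
46.4159,11.428,0.13203,0.31629,7.5266
50.1187,9.2447,0.13215,0.27716,6.3251
54.117,7.4629,0.13204,0.24247,5.2837
58.4341,6.0171,0.1317,0.21181,4.3936
63.0957,4.8469,0.13116,0.18474,3.6397
68.1292,3.9006,0.13042,0.16092,3.005
73.5642,3.136,0.12949,0.13998,2.4735
79.4328,2.5188,0.12838,0.12162,2.0305
85.7696,2.0188,0.1271,0.10554,1.661
92.6119,1.6174,0.12566,0.091496,1.3569
100,1.2956,0.12408,0.079241,1.1074
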