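# generated by scripts/generate_xs_tables.py; Cromer-Liberman photoabsorption, IT92 form factors, Waller-Hartree closure S(x,Z)
E_keV,sigma_pe,sigma_incoh,sigma_coh,mu_en_rho
1,4380.5,0.0033476,12.061,4380.5
1.07978,3782.5,0.0038483,11.996,3782.5
1.16591,3259.7,0.0044241,11.922,3259.7
1.25893,2803.2,0.0050771,11.839,2803.2
1.35936,2399,0.0058226,11.744,2399
1.4678,2045,0.0066635,11.637,2045
1.58489,1740.9,0.0076149,11.517,1740.9
1.71133,1480.3,0.0086807,11.383,1480.3
1.84785,1257,0.0098736,11.234,1257
1.99526,1065.9,0.011199,11.069,1065.9
2.12158,933.14,0.012359,10.926,933.14
2.12242,14136,0.012367,10.925,14136
2.15443,7211.6,0.012664,10.888,7211.6
2.20156,3321,0.013103,10.834,3321
2.20244,11605,0.013111,10.833,11605
2.32631,3219.1,0.014275,10.691,3219.1
2.51189,2669.3,0.016034,10.477,2669.3
2.64447,2347.3,0.017299,10.324,2347.3
2.64553,2739.3,0.017309,10.323,2739.3
2.71227,2570.8,0.017948,10.246,2570.8
2.92864,2128.6,0.020011,9.9993,2128.6
3.02539,1965,0.020931,9.8901,1965
3.02661,2094.2,0.020943,9.8888,2094.2
3.16228,1876.8,0.022232,9.7368,1876.8
3.29534,1698.3,0.023486,9.5897,1698.3
3.29666,1771.2,0.023498,9.5882,1771.2
3.41455,1629,0.0246,9.4597,1629
3.68695,1355.3,0.027122,9.1681,1355.3
3.98107,1126,0.029787,8.8636,1126
4.29866,933.7,0.032599,8.5467,933.7
4.64159,772.57,0.035545,8.2193,772.57
5,642.25,0.038525,7.8929,642.25
5.01187,638.47,0.038622,7.8823,638.47
5.4117,527.03,0.041815,7.5381,527.03
5.84341,434.49,0.045111,7.1884,434.49
6.30957,357.77,0.048495,6.8353,357.77
6.81292,294.28,0.051944,6.4814,294.28
7.35642,241.84,0.055452,6.1278,241.84
7.94328,198.59,0.058992,5.7772,198.59
8.57696,162.95,0.06257,5.4295,162.95
9.26119,133.54,0.066159,5.0871,133.54
10,109.3,0.06977,4.7497,109.3
10.7978,89.419,0.073375,4.4196,89.421
11.5614,74.753,0.076588,4.1317,74.755
11.566,196.77,0.076606,4.13,165.25
11.6591,192.54,0.07698,4.0968,161.95
12.5893,156.32,0.080538,3.7845,133.32
13.2699,135.39,0.082966,3.5758,116.49
13.2753,188.99,0.082985,3.5742,154.16
13.5936,177.21,0.084056,3.4828,145.31
13.8771,167.53,0.08498,3.4042,137.99
13.8827,193.62,0.084998,3.4027,157.85
14.678,168.04,0.08746,3.1955,138.68
15,158.93,0.08841,3.1165,131.76
15.8489,137.94,0.090763,2.9221,115.62
17.1133,113.1,0.093878,2.6665,96.157
18.4785,92.629,0.096831,2.4267,79.776
19.9526,75.782,0.099543,2.2058,66.045
20,75.312,0.099624,2.1992,65.658
21.5443,61.935,0.10205,2.0012,54.567
23.2631,50.566,0.10429,1.8144,44.996
25,41.764,0.10622,1.6519,37.485
25.1189,41.24,0.10634,1.6415,37.035
27.1227,33.595,0.10835,1.4757,30.424
29.2864,27.319,0.11031,1.3183,24.933
30,25.6,0.11089,1.2715,23.418
31.6228,22.203,0.1121,1.1732,20.409
34.1455,18.036,0.11371,1.04,16.688
35,16.866,0.11418,0.99999,15.637
36.8695,14.643,0.11508,0.92018,13.632
39.8107,11.882,0.11621,0.81227,11.125
40,11.729,0.11627,0.80599,10.986
42.9866,9.6362,0.11709,0.71601,9.0703
46.4159,7.8105,0.11773,0.62997,7.3886
50.1187,6.3271,0.11813,0.5535,6.0136
54.117,5.121,0.11831,0.48547,4.8892
58.4341,4.1425,0.11826,0.42519,3.9722
63.0957,3.3477,0.11801,0.37178,3.2238
68.1292,2.7043,0.11755,0.32463,2.6154
73.5642,2.1842,0.1169,0.28303,2.1216
78.3791,1.8306,0.11623,0.25247,1.7848
78.4105,9.0746,0.11623,0.25229,8.7918
79.4328,8.7666,0.11608,0.24644,8.4977
85.7696,7.2231,0.11508,0.21429,7.022
92.6119,5.9105,0.11392,0.18612,5.7623
100,4.832,0.11262,0.16146,4.7242
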