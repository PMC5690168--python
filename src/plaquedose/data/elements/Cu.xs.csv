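# generated by scripts/generate_xs_tables.py; Cromer-Liberman photoabsorption, IT92 form factors, Waller-Hartree closure S(x,Z)
E_keV,sigma_pe,sigma_incoh,sigma_coh,mu_en_rho
1,10923,0.0051363,5.0556,10923
1.07978,8778.6,0.0058932,5.0197,8778.6
1.16591,8269.2,0.0067563,4.9789,8269.2
1.25893,6875.5,0.0077288,4.9332,6875.5
1.35936,5706.4,0.0088282,4.8816,5706.4
1.4678,4725.2,0.010059,4.8242,4725.2
1.58489,3903.9,0.011436,4.7603,3903.9
1.71133,3220.4,0.012967,4.6898,3220.4
1.84785,2652.5,0.014664,4.6121,2652.5
1.99526,2181.3,0.016534,4.5272,2181.3
2.15443,1791,0.018588,4.4347,1791
2.32631,1468.2,0.020834,4.3345,1468.2
2.51189,1201.8,0.023282,4.2264,1201.8
2.71227,982.37,0.025943,4.1104,982.38
2.92864,801.94,0.028824,3.9862,801.94
3.16228,653.41,0.031939,3.8539,653.41
3.41455,531.74,0.035291,3.7136,531.74
3.68695,432.34,0.038895,3.5655,432.34
3.98107,351,0.04274,3.4102,351
4.29866,284.72,0.046835,3.2483,284.72
4.64159,230.8,0.051153,3.0812,230.8
5,188.13,0.055544,2.9153,188.13
5.01187,186.9,0.055688,2.9099,186.9
5.4117,151.24,0.060399,2.7362,151.24
5.84341,122.31,0.065255,2.5617,122.31
6.30957,98.862,0.070216,2.3882,98.863
6.81292,79.859,0.075226,2.2175,79.86
7.35642,64.471,0.080252,2.0509,64.473
7.94328,52.017,0.085216,1.8904,52.019
8.57696,41.943,0.090104,1.7365,41.945
8.9771,36.889,0.092918,1.6493,36.89
8.9807,297.73,0.092943,1.6485,193.65
9.26119,271.84,0.094819,1.5911,179.69
10,221.86,0.099368,1.4539,152.21
10.7978,181.75,0.10365,1.3265,128.91
11.6591,148.59,0.10769,1.2079,108.58
12.5893,121.08,0.11142,1.0992,90.893
13.5936,98.521,0.11487,0.99894,75.771
14.678,80.041,0.11801,0.90743,62.925
15,75.455,0.11885,0.88291,59.666
15.8489,64.929,0.12089,0.82335,52.072
17.1133,52.59,0.12351,0.7463,42.947
18.4785,42.518,0.12592,0.67534,35.299
19.9526,34.313,0.12812,0.60992,28.919
20,34.086,0.12818,0.60798,28.741
21.5443,27.658,0.13013,0.54946,23.633
23.2631,22.266,0.13198,0.49363,19.267
25,18.147,0.13357,0.44502,15.875
25.1189,17.903,0.13367,0.44193,15.672
27.1227,14.376,0.13524,0.39378,12.719
29.2864,11.524,0.1367,0.3492,10.296
30,10.75,0.13711,0.33611,9.6326
31.6228,9.2292,0.13793,0.30889,8.3211
34.1455,7.3844,0.13896,0.27249,6.7142
35,6.8712,0.13924,0.26164,6.2638
36.8695,5.9026,0.13974,0.24006,5.4094
39.8107,4.7108,0.1403,0.21111,4.3493
40,4.6451,0.14032,0.20943,4.2905
42.9866,3.7517,0.1406,0.18543,3.4884
46.4159,2.9863,0.14069,0.16262,2.7956
50.1187,2.3757,0.14054,0.14245,2.2389
54.117,1.8889,0.14018,0.1246,1.792
58.4341,1.501,0.13961,0.10884,1.4338
63.0957,1.1921,0.13885,0.094944,1.1469
68.1292,0.94625,0.1379,0.082719,0.91751
73.5642,0.75065,0.13677,0.071975,0.73421
79.4328,0.59514,0.13546,0.062554,0.58795
85.7696,0.47157,0.134,0.054305,0.47137
92.6119,0.37344,0.13239,0.047097,0.37857
100,0.29556,0.13063,0.040805,0.30479
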