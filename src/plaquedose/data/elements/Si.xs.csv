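# generated by scripts/generate_xs_tables.py; Cromer-Liberman photoabsorption, IT92 form factors, Waller-Hartree closure S(x,Z)
E_keV,sigma_pe,sigma_incoh,sigma_coh,mu_en_rho
1,1519,0.011794,2.5266,1519
1.07978,1240.4,0.013464,2.4895,1240.4
1.16591,1012,0.015331,2.4484,1012
1.25893,825.04,0.0174,2.4032,825.04
1.35936,672.04,0.019678,2.3539,672.04
1.4678,546.96,0.022175,2.3004,546.96
1.58489,444.78,0.024876,2.2431,444.78
1.71133,361.37,0.027794,2.182,361.37
1.83853,297.41,0.030684,2.1222,297.41
1.83927,3464.7,0.0307,2.1218,3314.9
1.84785,3436.8,0.030893,2.1179,3288.9
1.99526,2906.2,0.034186,2.0506,2790.4
2.15443,2381.7,0.037616,1.9814,2293.8
2.32631,1951,0.041196,1.9102,1884.3
2.51189,1599.4,0.044861,1.8383,1548.7
2.71227,1309.6,0.048622,1.7656,1271.2
2.92864,1070.3,0.052417,1.6931,1041.2
3.16228,872.58,0.056255,1.6209,850.64
3.41455,710.11,0.060094,1.5496,693.57
3.68695,576.92,0.06394,1.4791,564.48
3.98107,467.29,0.067778,1.4098,457.96
4.29866,378,0.071615,1.3416,371.01
4.64159,305.37,0.075466,1.2741,300.14
5,248.02,0.079225,1.2094,244.08
5.01187,246.38,0.079346,1.2074,242.47
5.4117,198.51,0.083281,1.1409,195.6
5.84341,159.74,0.087292,1.0747,157.57
6.30957,128.37,0.091399,1.0084,126.75
6.81292,103.02,0.095614,0.94225,101.82
7.35642,82.57,0.099935,0.87632,81.679
7.94328,66.09,0.10435,0.81097,65.431
8.57696,52.826,0.10884,0.74667,52.338
9.26119,42.132,0.11336,0.68408,41.773
10,33.542,0.11788,0.62361,33.278
10.7978,26.684,0.12231,0.56611,26.49
11.6591,21.212,0.12664,0.5117,21.07
12.5893,16.85,0.13074,0.46116,16.747
13.5936,13.375,0.13465,0.41423,13.301
14.678,10.609,0.13824,0.37141,10.555
15,9.9346,0.13922,0.35994,9.8863
15.8489,8.4083,0.14156,0.33224,8.3708
17.1133,6.6594,0.14451,0.29688,6.6335
18.4785,5.2703,0.14716,0.26483,5.2531
19.9526,4.1678,0.14946,0.23606,4.1571
20,4.1376,0.14952,0.23522,4.1271
21.5443,3.2935,0.15145,0.21014,3.2877
23.2631,2.6006,0.1531,0.18698,2.5986
25,2.0822,0.15441,0.16738,2.083
25.1189,2.0519,0.15449,0.16615,2.0529
27.1227,1.6176,0.1557,0.14707,1.6209
29.2864,1.2739,0.15675,0.12968,1.279
30,1.1817,0.15703,0.12459,1.1874
31.6228,1.0025,0.15758,0.11404,1.0091
34.1455,0.78834,0.15819,0.10003,0.79631
35,0.72953,0.15833,0.095859,0.73789
36.8695,0.61953,0.15855,0.087601,0.62866
39.8107,0.48653,0.15867,0.076592,0.4967
40,0.47931,0.15867,0.075955,0.48954
42.9866,0.38182,0.15856,0.066892,0.39296
46.4159,0.29944,0.15822,0.058343,0.31149
50.1187,0.23468,0.15765,0.050836,0.2476
54.117,0.18379,0.15688,0.044243,0.19756
58.4341,0.14384,0.1559,0.038469,0.15845
63.0957,0.1125,0.15474,0.033413,0.12794
68.1292,0.087922,0.15339,0.028997,0.10418
73.5642,0.068669,0.15187,0.025139,0.085746
79.4328,0.053596,0.15019,0.021781,0.071482
85.7696,0.041803,0.14835,0.018854,0.060493
92.6119,0.032582,0.14637,0.016314,0.052067
100,0.025379,0.14426,0.014104,0.045647
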