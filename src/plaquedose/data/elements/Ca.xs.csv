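# generated by scripts/generate_xs_tables.py; Cromer-Liberman photoabsorption, IT92 form factors, Waller-Hartree closure S(x,Z)
E_keV,sigma_pe,sigma_incoh,sigma_coh,mu_en_rho
1,4825.7,0.012808,3.5815,4825.7
1.07978,3969.1,0.014451,3.5296,3969.1
1.16591,3260.3,0.016241,3.4734,3260.3
1.25893,2674.6,0.018187,3.4127,2674.6
1.35936,2191.4,0.020279,3.348,2191.4
1.4678,1792.2,0.022526,3.279,1792.2
1.58489,1463.9,0.024914,3.2064,1463.9
1.71133,1194.6,0.027455,3.1299,1194.6
1.84785,973.58,0.030135,3.0499,973.58
1.99526,792.68,0.03297,2.9663,792.68
2.15443,644.85,0.035952,2.8793,644.85
2.32631,524.16,0.039097,2.7886,524.16
2.51189,425.72,0.042407,2.6945,425.72
2.71227,345.48,0.045899,2.5967,345.48
2.92864,280.14,0.049573,2.4954,280.15
3.16228,226.77,0.053447,2.3905,226.77
3.41455,183.37,0.057507,2.2825,183.37
3.68695,148.19,0.061764,2.1716,148.19
3.98107,119.69,0.066178,2.059,119.69
4.03729,115.1,0.066999,2.0383,115.1
4.03891,1091.2,0.067022,2.0377,944.39
4.29866,918.58,0.070744,1.9451,802.48
4.64159,754,0.075399,1.8315,665.75
5,621.64,0.079965,1.7226,554.09
5.01187,617.81,0.080112,1.7191,550.84
5.4117,505.25,0.084817,1.6092,454.53
5.84341,412.42,0.089457,1.503,374.08
6.30957,336.07,0.093991,1.4011,307.13
6.81292,273.37,0.098352,1.3045,251.57
7.35642,221.98,0.10255,1.213,205.58
7.94328,179.93,0.10652,1.1272,167.63
8.57696,145.59,0.11032,1.0462,136.37
9.26119,117.54,0.11393,0.97003,110.65
10,94.728,0.1174,0.89782,89.584
10.7978,76.257,0.12074,0.82921,72.423
11.6591,61.319,0.12399,0.7637,58.465
12.5893,49.251,0.12715,0.70102,47.129
13.5936,39.514,0.13026,0.64102,37.938
14.678,31.665,0.13328,0.58378,30.497
15,29.738,0.13412,0.56806,28.665
15.8489,25.347,0.13623,0.52928,24.482
17.1133,20.266,0.13906,0.47795,19.627
18.4785,16.176,0.14178,0.42969,15.706
19.9526,12.897,0.14432,0.38507,12.552
20,12.807,0.14439,0.38375,12.465
21.5443,10.275,0.14667,0.34383,10.022
23.2631,8.1781,0.14877,0.30643,7.9938
25,6.5967,0.15052,0.27436,6.4606
25.1189,6.5038,0.15063,0.27236,6.3705
27.1227,5.1647,0.15225,0.24152,5.0691
29.2864,4.0891,0.15364,0.21357,4.0217
30,3.8,0.15402,0.20541,3.7398
31.6228,3.2361,0.15476,0.1885,3.1896
34.1455,2.5599,0.15564,0.16599,2.5289
35,2.3735,0.15586,0.15928,2.3466
36.8695,2.0241,0.15624,0.14594,2.0046
39.8107,1.5997,0.15661,0.12807,1.5889
40,1.5766,0.15662,0.12704,1.5663
42.9866,1.2637,0.15671,0.11222,1.2595
46.4159,0.99783,0.15657,0.098169,0.99867
50.1187,0.78754,0.1562,0.085755,0.79227
54.117,0.62129,0.15561,0.074795,0.62908
58.4341,0.48991,0.15479,0.065152,0.50015
63.0957,0.38613,0.15377,0.056675,0.39838
68.1292,0.3042,0.15256,0.049245,0.31813
73.5642,0.23954,0.15116,0.042739,0.25492
79.4328,0.18854,0.14958,0.037058,0.20519
85.7696,0.14832,0.14784,0.032102,0.16612
92.6119,0.11663,0.14594,0.027788,0.13547
100,0.091672,0.1439,0.024037,0.11147
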