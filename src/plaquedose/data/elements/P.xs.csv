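# generated by scripts/generate_xs_tables.py; Cromer-Liberman photoabsorption, IT92 form factors, Waller-Hartree closure S(x,Z)
E_keV,sigma_pe,sigma_incoh,sigma_coh,mu_en_rho
1,1869.3,0.010387,2.6555,1869.3
1.07978,1527.3,0.011906,2.6193,1527.3
1.16591,1246.9,0.013619,2.5786,1246.9
1.25893,1017.1,0.015533,2.5336,1017.1
1.35936,828.94,0.017665,2.4838,828.94
1.4678,675.05,0.020022,2.4294,675.05
1.58489,549.27,0.022608,2.3703,549.27
1.71133,446.56,0.025433,2.3065,446.56
1.84785,362.74,0.028477,2.2387,362.74
1.99526,294.4,0.031751,2.1668,294.4
2.14507,241.59,0.035009,2.0961,241.59
2.14593,2695.9,0.035027,2.0957,2550.8
2.15443,2674.2,0.03521,2.0918,2530.9
2.32631,2236.7,0.038867,2.0138,2125.7
2.51189,1832.7,0.042655,1.9342,1748.4
2.71227,1501.4,0.046582,1.853,1437.4
2.92864,1229.9,0.050573,1.7717,1181.4
3.16228,1005.8,0.054632,1.6904,969.06
3.41455,821.02,0.05869,1.6102,793.25
3.68695,669.04,0.062746,1.5314,648.08
3.98107,544.27,0.066756,1.4545,528.48
4.29866,442.02,0.070715,1.3797,430.15
4.64159,357.89,0.074618,1.307,348.99
5,291.3,0.078346,1.2386,284.57
5.01187,289.39,0.078464,1.2364,282.72
5.4117,233.69,0.082279,1.1675,228.7
5.84341,188.46,0.086076,1.1002,184.73
6.30957,151.78,0.089887,1.0339,149
6.81292,122.07,0.093734,0.96844,120.01
7.35642,98.052,0.097634,0.90374,96.514
7.94328,78.651,0.1016,0.83978,77.509
8.57696,63.004,0.10562,0.77675,62.157
9.26119,50.394,0.10968,0.715,49.768
10,40.205,0.11378,0.65487,39.743
10.7978,32.048,0.11784,0.59703,31.708
11.6591,25.526,0.12186,0.5417,25.276
12.5893,20.314,0.12574,0.48966,20.131
13.5936,16.154,0.12949,0.44085,16.02
14.678,12.835,0.13298,0.39593,12.738
15,12.025,0.13394,0.38383,11.937
15.8489,10.19,0.13626,0.35452,10.12
17.1133,8.0832,0.13922,0.31701,8.0335
18.4785,6.4068,0.1419,0.28288,6.3721
19.9526,5.0739,0.14424,0.25221,5.0503
20,5.0374,0.1443,0.25131,5.0141
21.5443,4.0151,0.14628,0.22454,3.9998
23.2631,3.1746,0.148,0.19979,3.1655
25,2.5448,0.14936,0.1788,2.5402
25.1189,2.5079,0.14944,0.17749,2.5036
27.1227,1.9792,0.15071,0.15712,1.9785
29.2864,1.5593,0.1518,0.13858,1.5615
30,1.4468,0.15209,0.13316,1.4497
31.6228,1.2278,0.15266,0.12191,1.2322
34.1455,0.96622,0.15331,0.10697,0.97248
35,0.89437,0.15346,0.10253,0.90114
36.8695,0.75994,0.1537,0.093719,0.76772
39.8107,0.59736,0.15387,0.081964,0.60645
40,0.58853,0.15387,0.081285,0.59769
42.9866,0.46929,0.15379,0.071597,0.47953
46.4159,0.36847,0.1535,0.062454,0.37975
50.1187,0.28914,0.15298,0.05442,0.30139
54.117,0.22676,0.15226,0.04736,0.23992
58.4341,0.17774,0.15133,0.041175,0.19177
63.0957,0.13923,0.15022,0.035758,0.15412
68.1292,0.10901,0.14893,0.031026,0.12472
73.5642,0.085296,0.14747,0.026893,0.10183
79.4328,0.066704,0.14585,0.023295,0.08404
85.7696,0.052136,0.14407,0.020159,0.070263
92.6119,0.040726,0.14216,0.017439,0.059635
100,0.031795,0.14012,0.015072,0.051472
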