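# generated by scripts/generate_xs_tables.py; Cromer-Liberman photoabsorption, IT92 form factors, Waller-Hartree closure S(x,Z)
E_keV,sigma_pe,sigma_incoh,sigma_coh,mu_en_rho
1,3163,0.0070426,3.0407,3163
1.07978,2591.4,0.0081254,3.0092,2591.4
1.16591,2121,0.009368,2.9732,2121
1.25893,1734.4,0.010775,2.9328,1734.4
1.35936,1416.3,0.012377,2.8871,1416.3
1.4678,1155.4,0.014178,2.8361,1155.4
1.58489,941.71,0.016208,2.7791,941.71
1.71133,766.91,0.018472,2.7163,766.91
1.84785,624.03,0.020989,2.6473,624.03
1.99526,507.36,0.023769,2.572,507.36
2.15443,412.16,0.026809,2.4909,412.16
2.32631,334.55,0.030121,2.4039,334.55
2.51189,271.33,0.033679,2.312,271.33
2.71227,219.88,0.03749,2.2154,219.88
2.92864,178.04,0.041501,2.1157,178.04
3.16228,143.92,0.045714,2.013,143.92
3.20226,138.98,0.04642,1.996,138.98
3.20354,1387.4,0.046442,1.9955,1251.4
3.41455,1181.2,0.050053,1.9094,1072.6
3.68695,969.11,0.054509,1.8052,886.58
3.98107,793.88,0.059001,1.7023,731.27
4.29866,649.4,0.063506,1.6011,601.97
4.64159,530.43,0.067956,1.503,494.55
5,435.24,0.072183,1.4114,407.91
5.01187,432.49,0.072317,1.4086,405.4
5.4117,352.04,0.076554,1.3183,331.62
5.84341,286.06,0.080631,1.2326,270.7
6.30957,232.05,0.084553,1.1513,220.5
6.81292,187.81,0.0883,1.0746,179.16
7.35642,151.78,0.091908,1.0018,145.3
7.94328,122.49,0.095379,0.93272,117.65
8.57696,98.722,0.098755,0.86666,95.11
9.26119,79.414,0.10206,0.8033,76.724
10,63.78,0.10531,0.74226,61.78
10.7978,51.169,0.10852,0.68339,49.683
11.6591,41.007,0.1117,0.62661,39.905
12.5893,32.827,0.11484,0.57209,32.011
13.5936,26.25,0.11794,0.51989,25.647
14.678,20.951,0.12095,0.47046,20.506
15,19.652,0.12179,0.45695,19.245
15.8489,16.702,0.12388,0.42382,16.375
17.1133,13.304,0.12663,0.38053,13.065
18.4785,10.589,0.12924,0.34041,10.414
19.9526,8.421,0.13159,0.30393,8.2937
20,8.3615,0.13166,0.30285,8.2355
21.5443,6.6914,0.13373,0.2707,6.5996
23.2631,5.3127,0.13555,0.24096,5.2471
25,4.2754,0.13703,0.21572,4.2283
25.1189,4.2145,0.13712,0.21414,4.1685
27.1227,3.3406,0.13848,0.18979,3.3091
29.2864,2.6456,0.13965,0.16768,2.6249
30,2.4586,0.13997,0.16122,2.4407
31.6228,2.0935,0.14059,0.14781,2.081
34.1455,1.6552,0.14132,0.12997,1.6488
35,1.5344,0.14151,0.12465,1.5296
36.8695,1.3076,0.14181,0.11409,1.3059
39.8107,1.0321,0.14208,0.099966,1.034
40,1.0171,0.14209,0.099148,1.0192
42.9866,0.81401,0.14212,0.087463,0.81874
46.4159,0.64144,0.14194,0.076401,0.64844
50.1187,0.50504,0.14156,0.066651,0.51387
54.117,0.3973,0.14097,0.058064,0.40768
58.4341,0.31228,0.14019,0.050522,0.32398
63.0957,0.24525,0.13923,0.043905,0.25811
68.1292,0.19244,0.13809,0.038114,0.20634
73.5642,0.15088,0.13679,0.033051,0.16573
79.4328,0.11819,0.13533,0.028635,0.13394
85.7696,0.092508,0.13373,0.024786,0.10909
92.6119,0.072344,0.13199,0.021441,0.089733
100,0.056526,0.13012,0.018531,0.074685
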