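# generated by scripts/generate_xs_tables.py; Cromer-Liberman photoabsorption, IT92 form factors, Waller-Hartree closure S(x,Z)
E_keV,sigma_pe,sigma_incoh,sigma_coh,mu_en_rho
1,2381.3,0.009634,2.9459,2381.3
1.07978,1947.3,0.011074,2.909,1947.3
1.16591,1591.1,0.012711,2.8674,1591.1
1.25893,1298.8,0.014549,2.8209,1298.8
1.35936,1059.4,0.016616,2.7692,1059.4
1.4678,863.4,0.018918,2.712,863.4
1.58489,703.07,0.02147,2.6494,703.07
1.71133,572.04,0.024283,2.5811,572.04
1.84785,465.04,0.027351,2.5076,465.04
1.99526,377.74,0.030686,2.4289,377.74
2.15443,306.57,0.034257,2.3457,306.57
2.32631,248.59,0.038077,2.2583,248.59
2.47151,210.57,0.041223,2.1872,210.57
2.47249,2256.8,0.041245,2.1867,2107.8
2.51189,2177.6,0.042084,2.1679,2036.1
2.71227,1799.1,0.04629,2.0749,1690.8
2.92864,1474.3,0.050612,1.9808,1392.1
3.16228,1208.7,0.055055,1.8859,1146.3
3.41455,989.37,0.059532,1.7918,942.08
3.68695,808.41,0.064036,1.6988,772.63
3.98107,659.45,0.068498,1.6081,632.41
4.29866,537.03,0.072902,1.52,516.64
4.64159,436.56,0.077214,1.4349,421.21
5,356.53,0.081289,1.3557,344.89
5.01187,354.21,0.081418,1.3532,342.68
5.4117,286.66,0.085522,1.2746,278.01
5.84341,231.68,0.089524,1.199,225.21
6.30957,186.99,0.093458,1.1259,182.16
6.81292,150.72,0.097342,1.0551,147.12
7.35642,121.33,0.10121,0.98594,118.64
7.94328,97.529,0.10508,0.91831,95.526
8.57696,78.293,0.10897,0.85206,76.805
9.26119,62.748,0.11289,0.78721,61.645
10,50.221,0.11683,0.72394,49.404
10.7978,40.148,0.12077,0.66266,39.544
11.6591,32.029,0.12469,0.60361,31.584
12.5893,25.531,0.12852,0.54748,25.203
13.5936,20.334,0.13227,0.49433,20.094
14.678,16.181,0.13582,0.44491,16.005
15,15.167,0.1368,0.43153,15.006
15.8489,12.866,0.1392,0.399,12.738
17.1133,10.221,0.14229,0.35713,10.128
18.4785,8.113,0.14513,0.31884,8.0468
19.9526,6.4343,0.14763,0.28438,6.3876
20,6.3883,0.1477,0.28336,6.3421
21.5443,5.0986,0.14983,0.2532,5.0664
23.2631,4.0368,0.1517,0.22529,4.0153
25,3.24,0.1532,0.2016,3.2262
25.1189,3.1933,0.1533,0.20011,3.18
27.1227,2.5233,0.15468,0.17718,2.5161
29.2864,1.9905,0.15587,0.15633,1.988
30,1.8476,0.15619,0.15023,1.8463
31.6228,1.5693,0.15682,0.1376,1.5704
34.1455,1.2365,0.15754,0.1208,1.2404
35,1.1451,0.15771,0.1158,1.1497
36.8695,0.97378,0.15799,0.10589,0.97993
39.8107,0.7664,0.1582,0.09265,0.77441
40,0.75513,0.15821,0.091884,0.76324
42.9866,0.60284,0.15817,0.080961,0.6124
46.4159,0.4739,0.1579,0.070643,0.48481
50.1187,0.37233,0.1574,0.061567,0.38442
54.117,0.29235,0.15668,0.053588,0.30553
58.4341,0.22942,0.15576,0.046593,0.2436
63.0957,0.17993,0.15464,0.040464,0.19506
68.1292,0.14103,0.15332,0.035109,0.15707
73.5642,0.11047,0.15184,0.03043,0.1274
79.4328,0.086486,0.15018,0.026356,0.10427
85.7696,0.067667,0.14837,0.022806,0.08629
92.6119,0.052912,0.14641,0.019725,0.072355
100,0.041349,0.14431,0.017045,0.061595
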