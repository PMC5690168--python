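# generated by scripts/generate_xs_tables.py; Cromer-Liberman photoabsorption, IT92 form factors, Waller-Hartree closure S(x,Z)
E_keV,sigma_pe,sigma_incoh,sigma_coh,mu_en_rho
1,4036.6,0.011346,3.3472,4036.6
1.07978,3314.7,0.012762,3.3044,3314.7
1.16591,2718.5,0.014306,3.258,2718.5
1.25893,2225.1,0.015986,3.2078,2225.1
1.35936,1819.2,0.017806,3.1538,1819.2
1.4678,1485.9,0.019778,3.0957,1485.9
1.58489,1212.2,0.021909,3.0335,1212.2
1.71133,987.81,0.024214,2.9669,987.81
1.84785,804.3,0.026706,2.8955,804.3
1.99526,654.33,0.029401,2.8192,654.33
2.15443,531.89,0.032314,2.7377,531.89
2.32631,432.01,0.035461,2.6509,432.01
2.51189,350.61,0.038842,2.559,350.61
2.71227,284.31,0.042474,2.462,284.31
2.92864,230.37,0.046335,2.3607,230.37
3.16228,186.34,0.050435,2.2552,186.34
3.41455,150.58,0.054725,2.147,150.58
3.60668,129.3,0.057898,2.0683,129.3
3.60812,1255.1,0.057921,2.0678,1110.4
3.68695,1185,0.059205,2.0363,1051.3
3.98107,970.86,0.063805,1.9251,869.41
4.29866,796.07,0.068508,1.8139,719.03
4.64159,651.65,0.073234,1.7045,593.24
5,535.91,0.077799,1.6009,491.32
5.01187,532.56,0.077946,1.5976,488.36
5.4117,434.49,0.082582,1.4945,401.09
5.84341,353.86,0.087087,1.3959,328.67
6.30957,287.7,0.091442,1.302,268.73
6.81292,233.5,0.095597,1.2136,219.24
7.35642,189.16,0.099579,1.13,178.47
7.94328,152.96,0.10337,1.0513,144.95
8.57696,123.51,0.10701,0.97669,117.53
9.26119,99.54,0.11051,0.90586,95.071
10,80.081,0.11392,0.83815,76.752
10.7978,64.356,0.11725,0.77324,61.88
11.6591,51.662,0.12053,0.71086,49.822
12.5893,41.426,0.12375,0.65097,40.06
13.5936,33.181,0.12692,0.59354,32.169
14.678,26.548,0.13002,0.53888,25.799
15,24.92,0.13088,0.5239,24.233
15.8489,21.213,0.13303,0.48702,20.66
17.1133,16.92,0.13591,0.43849,16.513
18.4785,13.485,0.13865,0.39317,13.186
19.9526,10.738,0.14117,0.35162,10.519
20,10.662,0.14124,0.35039,10.446
21.5443,8.5432,0.14348,0.3135,8.3843
23.2631,6.7914,0.1455,0.27917,6.6765
25,5.4717,0.14717,0.2499,5.3877
25.1189,5.3942,0.14727,0.24807,5.312
27.1227,4.2784,0.1488,0.2199,4.2205
29.2864,3.384,0.15011,0.19436,3.3442
30,3.1438,0.15047,0.1869,3.1086
31.6228,2.6754,0.15117,0.17143,2.6491
34.1455,2.1142,0.15199,0.15085,2.0979
35,1.9596,0.1522,0.14471,1.946
36.8695,1.6699,0.15255,0.13252,1.6612
39.8107,1.3184,0.15288,0.1162,1.3154
40,1.2992,0.15289,0.11525,1.2966
42.9866,1.0404,0.15295,0.10174,1.0418
46.4159,0.82059,0.15279,0.088933,0.82544
50.1187,0.64693,0.1524,0.077633,0.6545
54.117,0.50979,0.15179,0.067668,0.51954
58.4341,0.40152,0.15098,0.058909,0.41308
63.0957,0.3161,0.14996,0.051217,0.32919
68.1292,0.24873,0.14876,0.044481,0.26315
73.5642,0.19563,0.14737,0.038588,0.21123
79.4328,0.15378,0.14582,0.033444,0.17046
85.7696,0.12083,0.1441,0.028961,0.1385
92.6119,0.094898,0.14224,0.025061,0.11349
100,0.074492,0.14024,0.02167,0.093956
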