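# generated by scripts/generate_xs_tables.py; Cromer-Liberman photoabsorption, IT92 form factors, Waller-Hartree closure S(x,Z)
E_keV,sigma_pe,sigma_incoh,sigma_coh,mu_en_rho
1,6519.4,0.0043915,7.6312,6519.4
1.07978,5488,0.0050697,7.5801,5488
1.16591,4610.7,0.0058494,7.5215,4610.7
1.25893,3865.9,0.0067336,7.4553,3865.9
1.35936,3235.1,0.007743,7.3801,3235.1
1.4678,2699.6,0.0088816,7.2956,2699.6
1.58489,2249.7,0.010171,7.2005,2249.7
1.71133,1872.3,0.011616,7.0947,1872.3
1.84785,1556.1,0.013235,6.9768,1556.1
1.99526,1291.5,0.015036,6.8468,1291.5
2.15443,1070.2,0.017032,6.7041,1070.2
2.32631,885.28,0.019231,6.5484,885.28
2.51189,731.34,0.021637,6.3798,731.34
2.71227,603.48,0.024258,6.1984,603.48
2.92864,497.41,0.027086,6.0052,497.41
3.16228,408.93,0.030129,5.8004,408.93
3.17267,405.5,0.030263,5.7914,405.5
3.17393,1323.5,0.03028,5.7903,1323.5
3.32963,1253.3,0.032281,5.6573,1253.3
3.33097,1691.1,0.032298,5.6562,1691.1
3.41455,1606.4,0.033361,5.586,1606.4
3.60358,1410,0.035744,5.4301,1410
3.60502,1620.1,0.035762,5.4289,1573.7
3.68695,1531.4,0.036787,5.3625,1488.5
3.98107,1263.1,0.040369,5.1325,1230.4
4.29866,1040.1,0.044103,4.897,1015.1
4.64159,854.57,0.047948,4.6589,835.57
5,705.2,0.05176,4.4269,690.64
5.01187,700.88,0.051884,4.4195,686.44
5.4117,574,0.055874,4.1812,563.05
5.84341,469.44,0.059886,3.9458,461.15
6.30957,383.42,0.063893,3.7149,377.15
6.81292,312.66,0.067849,3.4906,307.92
7.35642,254.63,0.071749,3.2732,251.06
7.94328,207.15,0.075545,3.0646,204.46
8.57696,168.36,0.079256,2.8638,166.33
9.26119,136.64,0.08285,2.6719,135.12
10,110.77,0.086362,2.4874,109.63
10.7978,89.732,0.089783,2.3104,88.876
11.6591,72.638,0.093144,2.1397,71.998
12.5893,58.766,0.096444,1.9752,58.287
13.5936,47.515,0.099702,1.8164,47.157
14.678,38.379,0.1029,1.6639,38.113
15,36.125,0.10379,1.6218,35.879
15.8489,30.974,0.10604,1.5177,30.776
17.1133,24.98,0.10907,1.3791,24.833
18.4785,20.139,0.112,1.248,20.03
19.9526,16.23,0.11474,1.1262,16.15
20,16.122,0.11483,1.1225,16.043
21.5443,13.075,0.11732,1.0129,13.017
23.2631,10.529,0.11963,0.90976,10.487
24.3454,9.2586,0.1209,0.8527,9.2252
24.3552,61.017,0.12091,0.85221,23.448
25,56.722,0.12161,0.82064,22.699
25.1189,55.99,0.12173,0.815,22.565
27.1227,45.784,0.12366,0.72737,20.473
29.2864,37.365,0.12544,0.64642,18.237
30,35.049,0.12595,0.62259,17.534
31.6228,30.452,0.12699,0.57295,16.017
34.1455,24.774,0.12833,0.50631,13.9
35,23.174,0.1287,0.48637,13.252
36.8695,20.128,0.1294,0.44666,11.949
39.8107,16.333,0.13023,0.39319,10.189
40,16.123,0.13028,0.39009,10.087
42.9866,13.236,0.13081,0.34561,8.6279
46.4159,10.712,0.13115,0.30323,7.2615
50.1187,8.6546,0.13125,0.26566,6.076
54.117,6.9797,0.13113,0.23236,5.0573
58.4341,5.6236,0.13078,0.20294,4.1928
63.0957,4.5266,0.13023,0.17698,3.4639
68.1292,3.64,0.12948,0.15414,2.8528
73.5642,2.9243,0.12855,0.13406,2.3429
79.4328,2.347,0.12744,0.11647,1.9193
85.7696,1.88,0.12616,0.10106,1.5674
92.6119,1.5054,0.12473,0.087604,1.2785
100,1.2053,0.12315,0.075863,1.042
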