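# generated by scripts/generate_xs_tables.py; Cromer-Liberman photoabsorption, IT92 form factors, Waller-Hartree closure S(x,Z)
E_keV,sigma_pe,sigma_incoh,sigma_coh,mu_en_rho
1,4573.7,0.007704,1.5011,4573.7
1.07978,3730.6,0.008903,1.4856,3730.6
1.16591,3038.3,0.010286,1.4678,3038.3
1.25893,2470.7,0.011857,1.4477,2470.7
1.35936,2006.1,0.013657,1.4249,2006.1
1.4678,1626.4,0.015693,1.3993,1626.4
1.58489,1316.5,0.018004,1.3705,1316.5
1.71133,1064,0.0206,1.3385,1064
1.84785,858.65,0.023516,1.3031,858.65
1.99526,691.86,0.026763,1.2642,691.86
2.15443,556.54,0.030361,1.2217,556.54
2.32631,446.78,0.034324,1.1758,446.78
2.51189,358.26,0.038646,1.1267,358.27
2.71227,286.95,0.043341,1.0745,286.95
2.92864,229.57,0.048369,1.02,229.57
3.16228,183.31,0.053739,0.96326,183.31
3.41455,146.17,0.059377,0.90528,146.17
3.68695,116.44,0.065281,0.8464,116.44
3.98107,92.663,0.071352,0.78762,92.663
4.29866,73.671,0.077567,0.72939,73.672
4.64159,58.515,0.083821,0.67258,58.516
5,46.766,0.089871,0.61933,46.767
5.01187,46.432,0.090066,0.61765,46.433
5.4117,36.808,0.096216,0.56517,36.809
5.84341,29.15,0.1022,0.51556,29.151
6.30957,23.063,0.10796,0.46899,23.064
6.81292,18.229,0.11343,0.42578,18.23
7.35642,14.394,0.1186,0.38579,14.396
7.94328,11.355,0.12339,0.34918,11.357
8.57696,8.9482,0.12784,0.31564,8.9507
9.26119,7.0444,0.13189,0.2852,7.0471
10,5.5408,0.1356,0.2575,5.5437
10.7978,4.3487,0.13894,0.23246,4.3519
11.6591,3.4114,0.14196,0.20976,3.4149
12.5893,2.6749,0.14467,0.18923,2.6787
13.5936,2.0964,0.14712,0.17061,2.1005
14.678,1.6423,0.14931,0.15369,1.6467
15,1.5326,0.14989,0.14919,1.5371
15.8489,1.2859,0.15129,0.13828,1.2907
17.1133,1.0064,0.15307,0.12423,1.0116
18.4785,0.78728,0.15468,0.11137,0.79286
19.9526,0.61559,0.15611,0.099628,0.6216
20,0.61092,0.15615,0.099282,0.61695
21.5443,0.48111,0.15738,0.088885,0.48759
23.2631,0.37584,0.15849,0.0791,0.38281
25,0.29799,0.15939,0.070705,0.30545
25.1189,0.29346,0.15944,0.070178,0.30096
27.1227,0.22891,0.16023,0.062076,0.23696
29.2864,0.17815,0.16087,0.054732,0.18678
30,0.16468,0.16102,0.052595,0.17349
31.6228,0.13863,0.1613,0.048179,0.14787
34.1455,0.10787,0.16153,0.042328,0.11774
35,0.099494,0.16156,0.040591,0.10957
36.8695,0.083925,0.16155,0.037149,0.094452
39.8107,0.065289,0.16137,0.032556,0.076495
40,0.064283,0.16135,0.032291,0.075532
42.9866,0.050786,0.16098,0.028503,0.062691
46.4159,0.039501,0.1604,0.024921,0.052124
50.1187,0.03072,0.15962,0.021765,0.044079
54.117,0.023889,0.15866,0.018985,0.037999
58.4341,0.018575,0.15752,0.016542,0.033448
63.0957,0.014442,0.15621,0.014396,0.03009
68.1292,0.011227,0.15473,0.012514,0.027658
73.5642,0.008727,0.1531,0.010868,0.025946
79.4328,0.006783,0.15131,0.0094284,0.024793
85.7696,0.0052715,0.14939,0.0081722,0.024071
92.6119,0.0040964,0.14733,0.0070786,0.023681
100,0.0031829,0.14515,0.0061259,0.023545
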