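# generated by scripts/generate_xs_tables.py; Cromer-Liberman photoabsorption, IT92 form factors, Waller-Hartree closure S(x,Z)
E_keV,sigma_pe,sigma_incoh,sigma_coh,mu_en_rho
1,865.6,0.011531,2.1478,865.6
1.07978,703.61,0.013086,2.1181,703.61
1.16591,571.68,0.014807,2.0856,571.68
1.25893,464.26,0.016701,2.05,464.26
1.30474,421.29,0.017639,2.0325,421.29
1.30526,5428.4,0.01765,2.0323,5284.1
1.35936,5343.8,0.018762,2.0116,5207.4
1.4678,4432.7,0.020998,1.9703,4327.9
1.58489,3627.5,0.023385,1.9265,3548
1.71133,2969.2,0.025935,1.8803,2909
1.84785,2437.6,0.028607,1.8323,2391.9
1.99526,1997.2,0.031413,1.7824,1962.5
2.15443,1633.1,0.03431,1.7314,1606.8
2.32631,1332.6,0.037311,1.6791,1312.8
2.51189,1085.3,0.040389,1.6261,1070.3
2.71227,881.87,0.043559,1.5721,870.59
2.92864,715.28,0.046822,1.5172,706.8
3.16228,578.71,0.050199,1.4611,572.36
3.41455,467.41,0.053713,1.4037,462.66
3.68695,377.04,0.057389,1.3446,373.49
3.98107,303.76,0.061251,1.2836,301.11
4.29866,244.42,0.065321,1.2207,242.45
4.64159,196.42,0.069605,1.156,194.95
5,158.73,0.073972,1.0917,157.63
5.01187,157.65,0.074115,1.0897,156.56
5.4117,126.37,0.07883,1.0221,125.56
5.84341,101.14,0.083741,0.95386,100.54
6.30957,80.816,0.08881,0.88556,80.372
6.81292,64.515,0.093994,0.81794,64.188
7.35642,51.452,0.099253,0.75165,51.211
7.94328,40.994,0.10451,0.68755,40.817
8.57696,32.629,0.10973,0.62603,32.499
9.26119,25.921,0.11481,0.56791,25.827
10,20.558,0.11974,0.51321,20.49
10.7978,16.293,0.1244,0.46258,16.244
11.6591,12.903,0.12882,0.41572,12.868
12.5893,10.211,0.13288,0.37303,10.187
13.5936,8.0752,0.13663,0.33403,8.0585
14.678,6.3812,0.13998,0.29885,6.3704
15,5.9694,0.14087,0.2895,5.96
15.8489,5.0389,0.143,0.267,5.0325
17.1133,3.976,0.14564,0.2384,3.973
18.4785,3.135,0.14797,0.21264,3.1346
19.9526,2.4701,0.14996,0.18952,2.4717
20,2.4519,0.15002,0.18885,2.4536
21.5443,1.9448,0.15168,0.16875,1.948
23.2631,1.53,0.1531,0.15014,1.5346
25,1.2209,0.15422,0.13437,1.2265
25.1189,1.2028,0.15429,0.13337,1.2086
27.1227,0.94492,0.15534,0.118,0.95163
29.2864,0.7418,0.15625,0.10397,0.7494
30,0.68749,0.15649,0.099864,0.69536
31.6228,0.58198,0.15694,0.091367,0.59043
34.1455,0.45632,0.15743,0.080093,0.46557
35,0.42188,0.15754,0.076746,0.43138
36.8695,0.35757,0.15769,0.070121,0.3676
39.8107,0.28002,0.15772,0.061298,0.29081
40,0.27582,0.15772,0.060789,0.28665
42.9866,0.21916,0.15753,0.053538,0.2307
46.4159,0.17142,0.15712,0.046704,0.18372
50.1187,0.13399,0.1565,0.040708,0.14706
54.117,0.10468,0.15568,0.035442,0.11851
58.4341,0.081725,0.15467,0.030832,0.096336
63.0957,0.063765,0.15347,0.026793,0.079158
68.1292,0.049722,0.1521,0.023265,0.065899
73.5642,0.038748,0.15057,0.020181,0.055712
79.4328,0.030177,0.14888,0.017494,0.047929
85.7696,0.023488,0.14704,0.015152,0.042024
92.6119,0.01827,0.14506,0.013116,0.037586
100,0.014203,0.14296,0.011347,0.03429
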