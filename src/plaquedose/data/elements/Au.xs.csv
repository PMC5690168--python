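# generated by scripts/generate_xs_tables.py; Cromer-Liberman photoabsorption, IT92 form factors, Waller-Hartree closure S(x,Z)
E_keV,sigma_pe,sigma_incoh,sigma_coh,mu_en_rho
1,4600,0.0032603,12.266,4600
1.07978,3972.2,0.0037504,12.202,3972.2
1.16591,3422.9,0.0043148,12.129,3422.9
1.25893,2944,0.0049556,12.046,2944
1.35936,2525.5,0.0056884,11.952,2525.5
1.4678,2157.2,0.0065161,11.845,2157.2
1.58489,1837.8,0.0074546,11.725,1837.8
1.71133,1561.9,0.0085076,11.591,1561.9
1.84785,1325.6,0.009689,11.441,1325.6
1.99526,1123.6,0.011004,11.275,1123.6
2.15443,950.96,0.012462,11.092,950.96
2.20556,903.41,0.012937,11.033,903.41
2.20644,12405,0.012945,11.032,12405
2.29054,3056.8,0.013732,10.934,3056.8
2.29146,10541,0.013741,10.933,10541
2.32631,5971.1,0.014069,10.893,5971.1
2.51189,2793.2,0.015827,10.676,2793.2
2.71227,2306.2,0.017745,10.441,2306.2
2.74245,2242.4,0.018034,10.406,2242.4
2.74355,2600.7,0.018045,10.405,2600.7
2.92864,2221,0.019817,10.19,2221
3.14737,1859.8,0.021909,9.9395,1859.8
3.14863,1980.3,0.021921,9.938,1980.3
3.16228,1959,0.022051,9.9225,1959
3.41455,1622,0.024437,9.6395,1622
3.42431,1610.8,0.024528,9.6287,1610.8
3.42568,1679.4,0.024541,9.6272,1679.4
3.68695,1408.8,0.02698,9.3415,1408.8
3.98107,1170.9,0.029669,9.0301,1170.9
4.29866,971.47,0.032507,8.7061,971.47
4.64159,804.44,0.035479,8.3714,804.44
5,668.9,0.038483,8.0379,668.9
5.01187,664.96,0.038581,8.0271,664.96
5.4117,549.1,0.041798,7.6757,549.1
5.84341,452.83,0.045114,7.3191,452.83
6.30957,373.04,0.048516,6.9594,373.05
6.81292,306.94,0.051978,6.5992,306.94
7.35642,252.31,0.055495,6.2398,252.31
7.94328,207.24,0.059037,5.8839,207.24
8.57696,170.09,0.062611,5.5314,170.09
9.26119,139.42,0.066191,5.1847,139.42
10,114.16,0.069789,4.8432,114.17
10.7978,93.414,0.073379,4.5092,93.416
11.6591,76.407,0.076969,4.1825,76.409
11.9163,72.158,0.077979,4.0916,72.16
11.9211,189.15,0.077997,4.0899,157.54
12.5893,162.81,0.080516,3.866,137.05
13.5936,132.1,0.084027,3.5597,112.75
13.7309,128.52,0.084478,3.5208,109.88
13.7363,179.62,0.084496,3.5192,145.12
14.3499,159.56,0.086438,3.3524,130.23
14.3557,184.39,0.086456,3.3509,148.9
14.678,174.3,0.087434,3.2676,141.48
15,164.96,0.088387,3.1872,134.57
15.8489,143.22,0.090748,2.9891,118.24
17.1133,117.49,0.093884,2.728,98.517
18.4785,96.275,0.096865,2.4828,81.879
19.9526,78.807,0.09961,2.2566,67.895
20,78.32,0.099692,2.2498,67.501
21.5443,64.443,0.10215,2.0468,56.181
23.2631,52.644,0.10443,1.8554,46.394
25,43.504,0.10638,1.6889,38.7
25.1189,42.96,0.10651,1.6781,38.238
27.1227,35.018,0.10855,1.5085,31.455
29.2864,28.495,0.11053,1.3476,25.812
30,26.706,0.11111,1.2997,24.252
31.6228,23.168,0.11233,1.1992,21.15
34.1455,18.827,0.11397,1.0631,17.31
35,17.608,0.11444,1.0222,16.225
36.8695,15.291,0.11535,0.94063,14.153
39.8107,12.413,0.1165,0.83033,11.56
40,12.254,0.11656,0.82391,11.416
42.9866,10.071,0.11738,0.73193,9.4327
46.4159,8.1665,0.11804,0.64397,7.6899
50.1187,6.6182,0.11845,0.56578,6.2636
54.117,5.3595,0.11863,0.49622,5.0967
58.4341,4.3374,0.11859,0.43459,4.1439
63.0957,3.5077,0.11834,0.37999,3.3663
68.1292,2.8347,0.11789,0.33178,2.7326
73.5642,2.2904,0.11724,0.28925,2.218
79.4328,1.8503,0.11642,0.25184,1.8002
80.7088,1.7701,0.11622,0.24467,1.7238
80.741,8.683,0.11622,0.24449,8.4002
85.7696,7.4412,0.11542,0.21898,7.2163
92.6119,6.1057,0.11426,0.19018,5.939
100,4.9973,0.11296,0.16498,4.8754
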