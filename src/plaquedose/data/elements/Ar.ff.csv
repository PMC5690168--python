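# generated by scripts/generate_xs_tables.py; Cromer-Liberman photoabsorption, IT92 form factors, Waller-Hartree closure S(x,Z)
x_invA,F,S
0,17.999,0
0.005,17.995,0.0064451
0.00584982,17.993,0.0085553
0.00684409,17.99,0.011443
0.00800734,17.987,0.015396
0.00936831,17.983,0.020801
0.0109606,17.976,0.028197
0.0128235,17.968,0.03831
0.015003,17.957,0.052136
0.017553,17.941,0.071019
0.0205364,17.919,0.096806
0.0240269,17.89,0.13197
0.0281106,17.85,0.17989
0.0328884,17.796,0.24504
0.0384783,17.722,0.33343
0.0450183,17.622,0.45295
0.0526698,17.487,0.61384
0.0616218,17.306,0.82913
0.0720953,17.066,1.1149
0.084349,16.75,1.49
0.0986853,16.338,1.9752
0.115458,15.813,2.5909
0.135082,15.159,3.3526
0.158041,14.368,4.2647
0.184903,13.449,5.3131
0.21633,12.428,6.4597
0.253098,11.357,7.6427
0.296116,10.302,8.7861
0.346445,9.3307,9.8183
0.405329,8.4913,10.693
0.47422,7.7893,11.412
0.554821,7.1757,12.03
0.649121,6.5644,12.635
0.759449,5.8811,13.298
0.888528,5.1015,14.036
1.03955,4.2525,14.813
1.21623,3.4005,15.563
1.42295,2.6369,16.204
1.6648,2.0501,16.672
1.94776,1.6841,16.951
2.27881,1.2657,17.256
2.66613,0.92467,17.489
3.11927,0.67553,17.65
3.64944,0.49351,17.76
4.26972,0.36054,17.835
4.99542,0.26339,17.887
5.84446,0.19242,17.922
6.83781,0.14058,17.947
8,0.1027,17.963
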