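# generated by scripts/generate_xs_tables.py; Cromer-Liberman photoabsorption, IT92 form factors, Waller-Hartree closure S(x,Z)
x_invA,F,S
0,78.957,0
0.005,78.947,0.063936
0.00584982,78.943,0.068568
0.00684409,78.938,0.074903
0.00800734,78.93,0.08358
0.00936831,78.92,0.095462
0.0109606,78.907,0.1117
0.0128235,78.888,0.13391
0.015003,78.863,0.16429
0.017553,78.828,0.20579
0.0205364,78.781,0.26248
0.0240269,78.717,0.33984
0.0281106,78.629,0.44527
0.0328884,78.509,0.58878
0.0384783,78.346,0.78366
0.0450183,78.126,1.0476
0.0526698,77.829,1.4036
0.0616218,77.429,1.8814
0.0720953,76.896,2.5182
0.084349,76.191,3.359
0.0986853,75.269,4.4557
0.115458,74.082,5.8637
0.135082,72.584,7.6358
0.158041,70.734,9.8124
0.184903,68.512,12.412
0.21633,65.918,15.426
0.253098,62.97,18.822
0.296116,59.692,22.562
0.346445,56.11,26.601
0.405329,52.274,30.87
0.47422,48.273,35.256
0.554821,44.215,39.631
0.649121,40.143,43.941
0.759449,36.003,48.234
0.888528,31.746,52.546
1.03955,27.473,56.758
1.21623,23.452,60.605
1.42295,19.972,63.83
1.6648,17.189,66.33
1.94776,15.094,68.16
2.27881,11.402,71.258
2.66613,8.3301,73.688
3.11927,6.0856,75.355
3.64944,4.4459,76.5
4.26972,3.248,77.284
4.99542,2.3728,77.823
5.84446,1.7335,78.192
6.83781,1.2664,78.446
8,0.92519,78.62
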