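# generated by scripts/generate_xs_tables.py; Cromer-Liberman photoabsorption, IT92 form factors, Waller-Hartree closure S(x,Z)
x_invA,F,S
0,10.992,0
0.005,10.988,0.014754
0.00584982,10.986,0.01683
0.00684409,10.984,0.019666
0.00800734,10.98,0.023543
0.00936831,10.976,0.02884
0.0109606,10.97,0.036068
0.0128235,10.962,0.045922
0.015003,10.951,0.059337
0.017553,10.935,0.077566
0.0205364,10.915,0.10226
0.0240269,10.887,0.13561
0.0281106,10.849,0.1804
0.0328884,10.799,0.24016
0.0384783,10.733,0.31917
0.0450183,10.647,0.42236
0.0526698,10.536,0.555
0.0616218,10.395,0.72194
0.0720953,10.222,0.92659
0.084349,10.016,1.1695
0.0986853,9.7794,1.4479
0.115458,9.5156,1.7563
0.135082,9.2273,2.0914
0.158041,8.9095,2.4582
0.184903,8.5455,2.8753
0.21633,8.1096,3.37
0.253098,7.5785,3.9657
0.296116,6.9413,4.6693
0.346445,6.2055,5.4659
0.405329,5.3984,6.3179
0.47422,4.5667,7.1696
0.554821,3.768,7.9588
0.649121,3.0562,8.6344
0.759449,2.4692,9.1686
0.888528,2.0245,9.5569
1.03955,1.7161,9.8165
1.21623,1.5099,9.985
1.42295,1.3538,10.11
1.6648,1.208,10.223
1.94776,1.0617,10.335
2.27881,0.79918,10.527
2.66613,0.58385,10.675
3.11927,0.42653,10.777
3.64944,0.31161,10.847
4.26972,0.22765,10.895
4.99542,0.16631,10.928
5.84446,0.1215,10.951
6.83781,0.088762,10.966
8,0.064846,10.977
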