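# generated by scripts/generate_xs_tables.py; Cromer-Liberman photoabsorption, IT92 form factors, Waller-Hartree closure S(x,Z)
x_invA,F,S
0,46.999,0
0.005,46.99,0.011874
0.00584982,46.987,0.015856
0.00684409,46.982,0.021299
0.00800734,46.976,0.028746
0.00936831,46.968,0.03893
0.0109606,46.956,0.052862
0.0128235,46.94,0.071887
0.015003,46.918,0.097885
0.017553,46.889,0.13337
0.0205364,46.849,0.18173
0.0240269,46.794,0.24758
0.0281106,46.719,0.33705
0.0328884,46.618,0.45829
0.0384783,46.481,0.62201
0.0450183,46.297,0.84203
0.0526698,46.052,1.1359
0.0616218,45.726,1.5252
0.0720953,45.297,2.0357
0.084349,44.742,2.6968
0.0986853,44.031,3.5401
0.115458,43.136,4.5978
0.135082,42.028,5.9009
0.158041,40.68,7.4775
0.184903,39.068,9.3503
0.21633,37.175,11.528
0.253098,35.012,13.991
0.296116,32.62,16.678
0.346445,30.079,19.489
0.405329,27.495,22.301
0.47422,24.986,24.981
0.554821,22.665,27.411
0.649121,20.59,29.543
0.759449,18.697,31.45
0.888528,16.816,33.309
1.03955,14.791,35.262
1.21623,12.61,37.308
1.42295,10.407,39.303
1.6648,8.4093,41.039
1.94776,6.8504,42.339
2.27881,5.1164,43.716
2.66613,3.7378,44.747
3.11927,2.7307,45.454
3.64944,1.9949,45.94
4.26972,1.4574,46.272
4.99542,1.0647,46.501
5.84446,0.77784,46.658
6.83781,0.56826,46.765
8,0.41515,46.839
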