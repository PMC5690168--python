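# generated by scripts/generate_xs_tables.py; Cromer-Liberman photoabsorption, IT92 form factors, Waller-Hartree closure S(x,Z)
x_invA,F,S
0,20,0
0.005,19.99,0.012386
0.00584982,19.986,0.016945
0.00684409,19.981,0.023179
0.00800734,19.974,0.031701
0.00936831,19.964,0.043331
0.0109606,19.951,0.059204
0.0128235,19.933,0.080841
0.015003,19.908,0.11028
0.017553,19.875,0.15025
0.0205364,19.83,0.20437
0.0240269,19.769,0.27735
0.0281106,19.687,0.37524
0.0328884,19.578,0.50558
0.0384783,19.434,0.67749
0.0450183,19.246,0.90135
0.0526698,19.005,1.1881
0.0616218,18.702,1.5476
0.0720953,18.33,1.9869
0.084349,17.887,2.5075
0.0986853,17.377,3.1049
0.115458,16.805,3.7701
0.135082,16.176,4.4963
0.158041,15.486,5.2859
0.184903,14.721,6.1539
0.21633,13.859,7.1217
0.253098,12.882,8.2026
0.296116,11.801,9.3808
0.346445,10.663,10.597
0.405329,9.555,11.757
0.47422,8.5677,12.768
0.554821,7.751,13.588
0.649121,7.0751,14.253
0.759449,6.4448,14.861
0.888528,5.765,15.505
1.03955,4.9958,16.215
1.21623,4.1584,16.963
1.42295,3.3169,17.684
1.6648,2.5614,18.302
1.94776,1.9794,18.754
2.27881,1.4654,19.131
2.66613,1.0706,19.404
3.11927,0.78212,19.591
3.64944,0.57138,19.719
4.26972,0.41743,19.807
4.99542,0.30496,19.868
5.84446,0.22279,19.909
6.83781,0.16276,19.938
8,0.1189,19.957
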