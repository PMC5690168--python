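# generated by scripts/generate_xs_tables.py; Cromer-Liberman photoabsorption, IT92 form factors, Waller-Hartree closure S(x,Z)
x_invA,F,S
0,6.9946,0
0.005,6.9923,0.0091817
0.00584982,6.9915,0.010177
0.00684409,6.9904,0.01154
0.00800734,6.9888,0.013406
0.00936831,6.9867,0.015956
0.0109606,6.9838,0.019446
0.0128235,6.9798,0.024219
0.015003,6.9744,0.030745
0.017553,6.9669,0.039658
0.0205364,6.9568,0.051833
0.0240269,6.9429,0.068439
0.0281106,6.924,0.09107
0.0328884,6.8983,0.12185
0.0384783,6.8634,0.16363
0.0450183,6.816,0.22016
0.0526698,6.7522,0.29632
0.0616218,6.6664,0.39834
0.0720953,6.5521,0.53393
0.084349,6.4012,0.71224
0.0986853,6.2045,0.94342
0.115458,5.9524,1.2375
0.135082,5.6368,1.6022
0.158041,5.2532,2.04
0.184903,4.8046,2.5438
0.21633,4.3047,3.0942
0.253098,3.7787,3.6596
0.296116,3.2595,4.2025
0.346445,2.7801,4.6887
0.405329,2.3657,5.0957
0.47422,2.0325,5.4128
0.554821,1.7863,5.6407
0.649121,1.6152,5.7954
0.759449,1.4874,5.9088
0.888528,1.3663,6.0145
1.03955,1.2301,6.1312
1.21623,1.0737,6.262
1.42295,0.90197,6.4013
1.6648,0.72421,6.5399
1.94776,0.55026,6.6691
2.27881,0.40188,6.7731
2.66613,0.29359,6.8443
3.11927,0.21449,6.8932
3.64944,0.1567,6.9267
4.26972,0.11447,6.9497
4.99542,0.083631,6.9655
5.84446,0.061097,6.9763
6.83781,0.044635,6.9838
8,0.032608,6.9889
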