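# generated by scripts/generate_xs_tables.py; Cromer-Liberman photoabsorption, IT92 form factors, Waller-Hartree closure S(x,Z)
x_invA,F,S
0,14.999,0
0.005,14.994,0.0076855
0.00584982,14.991,0.010208
0.00684409,14.989,0.013659
0.00800734,14.985,0.01838
0.00936831,14.979,0.024836
0.0109606,14.972,0.033661
0.0128235,14.962,0.04572
0.015003,14.948,0.062185
0.017553,14.929,0.084646
0.0205364,14.904,0.11525
0.0240269,14.869,0.15688
0.0281106,14.822,0.21338
0.0328884,14.758,0.28981
0.0384783,14.672,0.39278
0.0450183,14.556,0.53068
0.0526698,14.403,0.71395
0.0616218,14.2,0.95496
0.0720953,13.936,1.2675
0.084349,13.599,1.6653
0.0986853,13.177,2.1596
0.115458,12.666,2.7551
0.135082,12.068,3.4454
0.158041,11.399,4.2096
0.184903,10.688,5.0125
0.21633,9.9708,5.8113
0.253098,9.2833,6.5662
0.296116,8.6486,7.2533
0.346445,8.0652,7.876
0.405329,7.4998,8.4711
0.47422,6.8964,9.0962
0.554821,6.2076,9.7966
0.649121,5.4225,10.576
0.759449,4.5716,11.395
0.888528,3.7181,12.187
1.03955,2.9428,12.875
1.21623,2.3158,13.406
1.42295,1.864,13.772
1.6648,1.5618,14.007
1.94776,1.3615,14.157
2.27881,1.0284,14.398
2.66613,0.75132,14.587
3.11927,0.54888,14.717
3.64944,0.40099,14.806
4.26972,0.29295,14.867
4.99542,0.21401,14.909
5.84446,0.15635,14.937
6.83781,0.11422,14.957
8,0.083446,14.97
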