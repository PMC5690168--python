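# generated by scripts/generate_xs_tables.py; Cromer-Liberman photoabsorption, IT92 form factors, Waller-Hartree closure S(x,Z)
x_invA,F,S
0,18.999,0
0.005,18.99,0.012318
0.00584982,18.986,0.016407
0.00684409,18.982,0.022
0.00800734,18.975,0.029639
0.00936831,18.967,0.040061
0.0109606,18.955,0.054278
0.0128235,18.939,0.073623
0.015003,18.917,0.099923
0.017553,18.887,0.13556
0.0205364,18.847,0.18369
0.0240269,18.793,0.24838
0.0281106,18.721,0.33475
0.0328884,18.625,0.4491
0.0384783,18.5,0.59878
0.0450183,18.338,0.79188
0.0526698,18.132,1.0365
0.0616218,17.877,1.3396
0.0720953,17.567,1.7063
0.084349,17.2,2.1394
0.0986853,16.771,2.642
0.115458,16.274,3.2223
0.135082,15.692,3.8974
0.158041,15.001,4.6912
0.184903,14.184,5.6219
0.21633,13.237,6.6863
0.253098,12.183,7.8527
0.296116,11.073,9.0607
0.346445,9.9773,10.229
0.405329,8.9786,11.271
0.47422,8.1356,12.134
0.554821,7.444,12.828
0.649121,6.8278,13.436
0.759449,6.1866,14.057
0.888528,5.4587,14.746
1.03955,4.6434,15.497
1.21623,3.7877,16.257
1.42295,2.9725,16.949
1.6648,2.2917,17.499
1.94776,1.8163,17.864
2.27881,1.3543,18.201
2.66613,0.9894,18.452
3.11927,0.72282,18.624
3.64944,0.52806,18.742
4.26972,0.38578,18.823
4.99542,0.28183,18.879
5.84446,0.20589,18.917
6.83781,0.15042,18.943
8,0.10989,18.961
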