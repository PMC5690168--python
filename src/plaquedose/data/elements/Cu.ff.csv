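# generated by scripts/generate_xs_tables.py; Cromer-Liberman photoabsorption, IT92 form factors, Waller-Hartree closure S(x,Z)
x_invA,F,S
0,28.986,0
0.005,28.98,0.023576
0.00584982,28.978,0.026031
0.00684409,28.976,0.029388
0.00800734,28.972,0.033981
0.00936831,28.966,0.040263
0.0109606,28.959,0.048853
0.0128235,28.949,0.060593
0.015003,28.936,0.076633
0.017553,28.918,0.098531
0.0205364,28.893,0.1284
0.0240269,28.859,0.16908
0.0281106,28.813,0.22438
0.0328884,28.75,0.29939
0.0384783,28.666,0.40078
0.0450183,28.552,0.53724
0.0526698,28.399,0.71979
0.0616218,28.196,0.96209
0.0720953,27.929,1.2804
0.084349,27.582,1.6932
0.0986853,27.138,2.2197
0.115458,26.581,2.8785
0.135082,25.895,3.6854
0.158041,25.067,4.6532
0.184903,24.085,5.7935
0.21633,22.93,7.1217
0.253098,21.581,8.6571
0.296116,20.02,10.41
0.346445,18.256,12.358
0.405329,16.341,14.43
0.47422,14.363,16.52
0.554821,12.429,18.508
0.649121,10.644,20.29
0.759449,9.1038,21.779
0.888528,7.8777,22.93
1.03955,6.9572,23.771
1.21623,6.2315,24.418
1.42295,5.5473,25.015
1.6648,4.8063,25.645
1.94776,3.9991,26.309
2.27881,2.973,27.115
2.66613,2.1719,27.707
3.11927,1.5867,28.113
3.64944,1.1592,28.391
4.26972,0.84686,28.582
4.99542,0.61868,28.713
5.84446,0.45198,28.803
6.83781,0.3302,28.865
8,0.24123,28.907
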