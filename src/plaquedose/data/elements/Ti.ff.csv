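# generated by scripts/generate_xs_tables.py; Cromer-Liberman photoabsorption, IT92 form factors, Waller-Hartree closure S(x,Z)
x_invA,F,S
0,21.997,0
0.005,21.988,0.014199
0.00584982,21.985,0.018193
0.00684409,21.98,0.023653
0.00800734,21.974,0.031115
0.00936831,21.966,0.041316
0.0109606,21.954,0.055247
0.0128235,21.938,0.074254
0.015003,21.917,0.10016
0.017553,21.887,0.13542
0.0205364,21.847,0.18329
0.0240269,21.793,0.24812
0.0281106,21.72,0.33555
0.0328884,21.622,0.45285
0.0384783,21.491,0.60909
0.0450183,21.319,0.81524
0.0526698,21.093,1.0838
0.0616218,20.803,1.428
0.0720953,20.439,1.8599
0.084349,19.991,2.3882
0.0986853,19.457,3.0154
0.115458,18.839,3.7369
0.135082,18.142,4.5442
0.158041,17.369,5.4326
0.184903,16.512,6.4086
0.21633,15.554,7.488
0.253098,14.481,8.6806
0.296116,13.299,9.9749
0.346445,12.035,11.333
0.405329,10.748,12.686
0.47422,9.5246,13.944
0.554821,8.4579,15.014
0.649121,7.5962,15.859
0.759449,6.8991,16.529
0.888528,6.2573,17.134
1.03955,5.5679,17.77
1.21623,4.7917,18.467
1.42295,3.9534,19.195
1.6648,3.1206,19.888
1.94776,2.3843,20.471
2.27881,1.7533,20.943
2.66613,1.2809,21.275
3.11927,0.93576,21.502
3.64944,0.68363,21.659
4.26972,0.49943,21.766
4.99542,0.36486,21.839
5.84446,0.26655,21.89
6.83781,0.19473,21.924
8,0.14226,21.948
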