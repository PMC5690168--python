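# generated by scripts/generate_xs_tables.py; Cromer-Liberman photoabsorption, IT92 form factors, Waller-Hartree closure S(x,Z)
x_invA,F,S
0,5.9992,0
0.005,5.9966,0.0040824
0.00584982,5.9956,0.0052341
0.00684409,5.9943,0.0068086
0.00800734,5.9925,0.008963
0.00936831,5.9901,0.01191
0.0109606,5.9867,0.01594
0.0128235,5.9821,0.021449
0.015003,5.9758,0.028975
0.017553,5.9673,0.03925
0.0205364,5.9556,0.053264
0.0240269,5.9396,0.072354
0.0281106,5.918,0.098311
0.0328884,5.8885,0.13352
0.0384783,5.8487,0.18112
0.0450183,5.795,0.24519
0.0526698,5.723,0.33089
0.0616218,5.6272,0.44459
0.0720953,5.501,0.59376
0.084349,5.3369,0.7866
0.0986853,5.1276,1.031
0.115458,4.8665,1.3331
0.135082,4.5507,1.6941
0.158041,4.1828,2.1084
0.184903,3.7738,2.5605
0.21633,3.3431,3.0259
0.253098,2.9172,3.4746
0.296116,2.5244,3.8769
0.346445,2.19,4.2098
0.405329,1.9286,4.4631
0.47422,1.7375,4.6439
0.554821,1.5969,4.7745
0.649121,1.4799,4.8815
0.759449,1.3628,4.9868
0.888528,1.2299,5.1042
1.03955,1.0748,5.2379
1.21623,0.90057,5.3837
1.42295,0.71786,5.5305
1.6648,0.54406,5.6634
1.94776,0.39926,5.7678
2.27881,0.29188,5.8406
2.66613,0.21324,5.8906
3.11927,0.15578,5.9249
3.64944,0.11381,5.9485
4.26972,0.083143,5.9647
4.99542,0.060741,5.9758
5.84446,0.044375,5.9834
6.83781,0.032418,5.9886
8,0.023683,5.9922
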