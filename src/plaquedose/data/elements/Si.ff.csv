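# generated by scripts/generate_xs_tables.py; Cromer-Liberman photoabsorption, IT92 form factors, Waller-Hartree closure S(x,Z)
x_invA,F,S
0,13.998,0
0.005,13.992,0.010097
0.00584982,13.989,0.012755
0.00684409,13.986,0.016392
0.00800734,13.982,0.021366
0.00936831,13.977,0.028165
0.0109606,13.969,0.037458
0.0128235,13.958,0.050149
0.015003,13.944,0.067467
0.017553,13.924,0.091072
0.0205364,13.897,0.12319
0.0240269,13.861,0.16681
0.0281106,13.812,0.22588
0.0328884,13.745,0.30554
0.0384783,13.655,0.41239
0.0450183,13.536,0.55471
0.0526698,13.379,0.74239
0.0616218,13.173,0.98669
0.0720953,12.909,1.2992
0.084349,12.577,1.69
0.0986853,12.171,2.1646
0.115458,11.693,2.7203
0.135082,11.153,3.3432
0.158041,10.57,4.0078
0.184903,9.9716,4.6826
0.21633,9.3827,5.339
0.253098,8.8176,5.9612
0.296116,8.2746,6.5515
0.346445,7.732,7.1337
0.405329,7.1496,7.7496
0.47422,6.4861,8.439
0.554821,5.7249,9.2126
0.649121,4.8869,10.041
0.759449,4.0271,10.861
0.888528,3.2224,11.598
1.03955,2.5473,12.188
1.21623,2.0404,12.612
1.42295,1.6893,12.893
1.6648,1.4514,13.078
1.94776,1.2929,13.197
2.27881,0.98047,13.424
2.66613,0.71629,13.605
3.11927,0.52329,13.729
3.64944,0.38229,13.814
4.26972,0.27929,13.872
4.99542,0.20404,13.912
5.84446,0.14906,13.94
6.83781,0.1089,13.959
8,0.079555,13.972
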