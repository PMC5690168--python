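# generated by scripts/generate_xs_tables.py; Cromer-Liberman photoabsorption, IT92 form factors, Waller-Hartree closure S(x,Z)
x_invA,F,S
0,16,0
0.005,15.994,0.0066923
0.00584982,15.992,0.0090713
0.00684409,15.99,0.012326
0.00800734,15.986,0.016777
0.00936831,15.981,0.022866
0.0109606,15.974,0.031193
0.0128235,15.965,0.042574
0.015003,15.952,0.058121
0.017553,15.934,0.079343
0.0205364,15.91,0.10828
0.0240269,15.877,0.1477
0.0281106,15.832,0.20128
0.0328884,15.771,0.27393
0.0384783,15.689,0.37209
0.0450183,15.579,0.50411
0.0526698,15.431,0.68053
0.0616218,15.234,0.91427
0.0720953,14.976,1.2204
0.084349,14.642,1.6153
0.0986853,14.218,2.1143
0.115458,13.691,2.7288
0.135082,13.059,3.4604
0.158041,12.33,4.2961
0.184903,11.527,5.2049
0.21633,10.689,6.1394
0.253098,9.8645,7.045
0.296116,9.0979,7.8735
0.346445,8.4151,8.5998
0.405329,7.8071,9.2366
0.47422,7.2241,9.838
0.554821,6.5972,10.474
0.649121,5.8797,11.187
0.759449,5.0705,11.971
0.888528,4.211,12.776
1.03955,3.3735,13.529
1.21623,2.6424,14.157
1.42295,2.0808,14.616
1.6648,1.697,14.917
1.94776,1.4427,15.108
2.27881,1.0844,15.367
2.66613,0.79219,15.566
3.11927,0.57874,15.702
3.64944,0.42281,15.796
4.26972,0.30888,15.86
4.99542,0.22566,15.904
5.84446,0.16486,15.934
6.83781,0.12044,15.955
8,0.087986,15.969
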