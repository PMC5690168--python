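# generated by scripts/generate_xs_tables.py; Cromer-Liberman photoabsorption, IT92 form factors, Waller-Hartree closure S(x,Z)
x_invA,F,S
0,11.986,0
0.005,11.981,0.022331
0.00584982,11.98,0.02459
0.00684409,11.977,0.02768
0.00800734,11.973,0.031906
0.00936831,11.969,0.03768
0.0109606,11.962,0.045572
0.0128235,11.953,0.056342
0.015003,11.941,0.071029
0.017553,11.924,0.091033
0.0205364,11.901,0.11823
0.0240269,11.871,0.15509
0.0281106,11.829,0.20491
0.0328884,11.773,0.2719
0.0384783,11.698,0.36142
0.0450183,11.599,0.48
0.0526698,11.468,0.63523
0.0616218,11.3,0.8353
0.0720953,11.086,1.0878
0.084349,10.823,1.3978
0.0986853,10.51,1.7655
0.115458,10.151,2.1832
0.135082,9.7598,2.6353
0.158041,9.3525,3.1023
0.184903,8.9392,3.572
0.21633,8.5132,4.0517
0.253098,8.0471,4.571
0.296116,7.5052,5.1673
0.346445,6.8642,5.8614
0.405329,6.1249,6.646
0.47422,5.3122,7.4867
0.554821,4.4716,8.3295
0.649121,3.6615,9.1123
0.759449,2.941,9.78
0.888528,2.3561,10.299
1.03955,1.9277,10.663
1.21623,1.6397,10.899
1.42295,1.4436,11.055
1.6648,1.2876,11.176
1.94776,1.1479,11.282
2.27881,0.86729,11.487
2.66613,0.6336,11.648
3.11927,0.46288,11.759
3.64944,0.33816,11.834
4.26972,0.24705,11.886
4.99542,0.18048,11.922
5.84446,0.13185,11.947
6.83781,0.096326,11.963
8,0.070372,11.975
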