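# generated by scripts/generate_xs_tables.py; Cromer-Liberman photoabsorption, IT92 form factors, Waller-Hartree closure S(x,Z)
x_invA,F,S
0,46.001,0
0.005,45.993,0.0086287
0.00584982,45.99,0.01213
0.00684409,45.986,0.016937
0.00800734,45.98,0.02351
0.00936831,45.973,0.032499
0.0109606,45.963,0.044793
0.0128235,45.949,0.061604
0.015003,45.929,0.084591
0.017553,45.903,0.11599
0.0205364,45.868,0.15886
0.0240269,45.819,0.21734
0.0281106,45.752,0.29699
0.0328884,45.662,0.40532
0.0384783,45.539,0.55228
0.0450183,45.373,0.75103
0.0526698,45.15,1.0187
0.0616218,44.85,1.377
0.0720953,44.45,1.8533
0.084349,43.924,2.4802
0.0986853,43.237,3.295
0.115458,42.356,4.3377
0.135082,41.244,5.6467
0.158041,39.871,7.2529
0.184903,38.219,9.1719
0.21633,36.286,11.395
0.253098,34.102,13.88
0.296116,31.724,16.548
0.346445,29.242,19.291
0.405329,26.758,21.99
0.47422,24.376,24.531
0.554821,22.184,26.826
0.649121,20.203,28.862
0.759449,18.341,30.74
0.888528,16.43,32.627
1.03955,14.355,34.628
1.21623,12.144,36.696
1.42295,9.9639,38.662
1.6648,8.0541,40.316
1.94776,6.631,41.499
2.27881,4.9666,42.818
2.66613,3.6284,43.817
3.11927,2.6507,44.502
3.64944,1.9365,44.972
4.26972,1.4147,45.295
4.99542,1.0335,45.516
5.84446,0.75507,45.668
6.83781,0.55162,45.772
8,0.40299,45.844
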