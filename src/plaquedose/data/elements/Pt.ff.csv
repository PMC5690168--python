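# generated by scripts/generate_xs_tables.py; Cromer-Liberman photoabsorption, IT92 form factors, Waller-Hartree closure S(x,Z)
x_invA,F,S
0,77.955,0
0.005,77.944,0.066929
0.00584982,77.94,0.071662
0.00684409,77.935,0.078115
0.00800734,77.928,0.086967
0.00936831,77.917,0.099068
0.0109606,77.904,0.11563
0.0128235,77.885,0.13827
0.015003,77.859,0.16922
0.017553,77.824,0.21151
0.0205364,77.776,0.26926
0.0240269,77.71,0.34805
0.0281106,77.62,0.45542
0.0328884,77.498,0.60147
0.0384783,77.333,0.79972
0.0450183,77.109,1.068
0.0526698,76.807,1.4296
0.0616218,76.402,1.9141
0.0720953,75.862,2.5587
0.084349,75.15,3.4078
0.0986853,74.222,4.5119
0.115458,73.031,5.9237
0.135082,71.535,7.6919
0.158041,69.7,9.8514
0.184903,67.508,12.415
0.21633,64.963,15.371
0.253098,62.08,18.69
0.296116,58.877,22.344
0.346445,55.367,26.301
0.405329,51.592,30.502
0.47422,47.638,34.836
0.554821,43.606,39.181
0.649121,39.537,43.487
0.759449,35.383,47.791
0.888528,31.122,52.102
1.03955,26.886,56.273
1.21623,22.954,60.027
1.42295,19.601,63.129
1.6648,16.94,65.518
1.94776,14.913,67.288
2.27881,11.267,70.349
2.66613,8.2311,72.75
3.11927,6.0133,74.398
3.64944,4.393,75.529
4.26972,3.2094,76.305
4.99542,2.3446,76.837
5.84446,1.7129,77.202
6.83781,1.2514,77.452
8,0.91419,77.624
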