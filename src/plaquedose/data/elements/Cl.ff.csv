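# generated by scripts/generate_xs_tables.py; Cromer-Liberman photoabsorption, IT92 form factors, Waller-Hartree closure S(x,Z)
x_invA,F,S
0,17,0
0.005,16.995,0.0054862
0.00584982,16.994,0.0077313
0.00684409,16.991,0.010803
0.00800734,16.987,0.015002
0.00936831,16.983,0.020748
0.0109606,16.976,0.028609
0.0128235,16.967,0.039353
0.015003,16.955,0.054034
0.017553,16.938,0.074087
0.0205364,16.915,0.10145
0.0240269,16.884,0.13875
0.0281106,16.842,0.18951
0.0328884,16.784,0.25844
0.0384783,16.706,0.35179
0.0450183,16.601,0.4777
0.0526698,16.459,0.64664
0.0616218,16.27,0.87169
0.0720953,16.02,1.1686
0.084349,15.694,1.5552
0.0986853,15.274,2.0502
0.115458,14.744,2.6696
0.135082,14.096,3.4228
0.158041,13.328,4.3055
0.184903,12.456,5.2946
0.21633,11.517,6.3459
0.253098,10.561,7.3982
0.296116,9.6476,8.3859
0.346445,8.828,9.2564
0.405329,8.1242,9.9912
0.47422,7.5097,10.622
0.554821,6.9131,11.225
0.649121,6.258,11.876
0.759449,5.5074,12.604
0.888528,4.6752,13.389
1.03955,3.8157,14.17
1.21623,3.0102,14.871
1.42295,2.3428,15.424
1.6648,1.8614,15.804
1.94776,1.5459,16.043
2.27881,1.1584,16.323
2.66613,0.84625,16.536
3.11927,0.61823,16.681
3.64944,0.45165,16.781
4.26972,0.32996,16.85
4.99542,0.24105,16.897
5.84446,0.1761,16.929
6.83781,0.12865,16.952
8,0.093989,16.967
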