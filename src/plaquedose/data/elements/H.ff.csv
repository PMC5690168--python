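# generated by scripts/generate_xs_tables.py; Cromer-Liberman photoabsorption, IT92 form factors, Waller-Hartree closure S(x,Z)
x_invA,F,S
0,0.99995,0
0.005,0.99954,0.00054872
0.00584982,0.99939,0.0007303
0.00684409,0.99918,0.0009786
0.00800734,0.9989,0.0013185
0.00936831,0.99851,0.0017833
0.0109606,0.99798,0.0024192
0.0128235,0.99726,0.0032885
0.015003,0.99627,0.0044767
0.017553,0.99491,0.0061
0.0205364,0.99307,0.0083155
0.0240269,0.99054,0.011337
0.0281106,0.98711,0.015451
0.0328884,0.98243,0.021043
0.0384783,0.97609,0.028623
0.0450183,0.96751,0.038862
0.0526698,0.95595,0.052627
0.0616218,0.94046,0.071014
0.0720953,0.91988,0.09536
0.084349,0.8928,0.12722
0.0986853,0.85765,0.16829
0.115458,0.81285,0.22014
0.135082,0.75706,0.28393
0.158041,0.6896,0.3598
0.184903,0.61096,0.44637
0.21633,0.52332,0.54025
0.253098,0.43068,0.63609
0.296116,0.33854,0.72739
0.346445,0.25288,0.80791
0.405329,0.17879,0.87329
0.47422,0.11947,0.92189
0.554821,0.075824,0.95473
0.649121,0.046222,0.97501
0.759449,0.027074,0.98685
0.888528,0.014891,0.99358
1.03955,0.007742,0.99707
1.21623,0.0043809,0.99852
1.42295,0.0032798,0.99896
1.6648,0.0030611,0.99904
1.94776,0.0030389,0.99905
2.27881,0.0023405,0.9993
2.66613,0.0017098,0.99952
3.11927,0.0012491,0.99967
3.64944,0.00091257,0.99977
4.26972,0.00066668,0.99985
4.99542,0.00048705,0.99989
5.84446,0.00035582,0.99993
6.83781,0.00025995,0.99995
8,0.00018991,0.99997
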