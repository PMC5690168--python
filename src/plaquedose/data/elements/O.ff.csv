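# generated by scripts/generate_xs_tables.py; Cromer-Liberman photoabsorption, IT92 form factors, Waller-Hartree closure S(x,Z)
x_invA,F,S
0,7.9994,0
0.005,7.9973,0.0031951
0.00584982,7.9966,0.0041083
0.00684409,7.9955,0.0053573
0.00800734,7.9941,0.0070668
0.00936831,7.9922,0.0094055
0.0109606,7.9895,0.012605
0.0128235,7.9858,0.01698
0.015003,7.9809,0.022964
0.017553,7.974,0.031141
0.0205364,7.9647,0.042312
0.0240269,7.952,0.05756
0.0281106,7.9347,0.078352
0.0328884,7.911,0.10666
0.0384783,7.8789,0.14514
0.0450183,7.8352,0.1973
0.0526698,7.7762,0.26775
0.0616218,7.6968,0.36245
0.0720953,7.5904,0.48893
0.084349,7.4492,0.65636
0.0986853,7.2635,0.87543
0.115458,7.023,1.1576
0.135082,6.717,1.5137
0.158041,6.3371,1.9514
0.184903,5.8795,2.4717
0.21633,5.3487,3.0651
0.253098,4.7601,3.7093
0.296116,4.141,4.37
0.346445,3.5279,5.005
0.405329,2.9613,5.5725
0.47422,2.4774,6.0403
0.554821,2.097,6.3956
0.649121,1.8182,6.6481
0.759449,1.6204,6.8226
0.888528,1.4737,6.9493
1.03955,1.3453,7.0582
1.21623,1.209,7.1715
1.42295,1.0534,7.2978
1.6648,0.88092,7.4334
1.94776,0.70331,7.5675
2.27881,0.51922,7.6995
2.66613,0.37932,7.7938
3.11927,0.27712,7.8586
3.64944,0.20245,7.903
4.26972,0.1479,7.9334
4.99542,0.10805,7.9543
5.84446,0.078937,7.9687
6.83781,0.057668,7.9785
8,0.04213,7.9852
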