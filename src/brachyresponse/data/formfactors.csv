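Z,a1,a2,a3,a4,b1,b2,b3,b4,c
1,0.493002,0.322912,0.140191,0.04081,10.5109,26.1257,3.14236,57.7997,0.003038
3,1.1282,0.7508,0.6175,0.4653,3.9546,1.0524,85.3905,168.261,0.0377
5,2.0545,1.3326,1.0979,0.7068,23.2185,1.021,60.3498,0.1403,-0.1932
6,2.31,1.02,1.5886,0.865,20.8439,10.2075,0.5687,51.6512,0.2156
7,12.2126,3.1322,2.0125,1.1663,0.0057,9.8933,28.9975,0.5826,-11.529
8,3.0485,2.2868,1.5463,0.867,13.2771,5.7011,0.3239,32.9089,0.2508
9,3.5392,2.6412,1.517,1.0243,10.2825,4.2944,0.2615,26.1476,0.2776
13,6.4202,1.9002,1.5936,1.9646,3.0387,0.7426,31.5472,85.0886,1.1151
14,6.2915,3.0353,1.9891,1.541,2.4386,32.3337,0.6785,81.6937,1.1407
18,7.4845,6.7723,0.6539,1.6442,0.9072,14.8407,43.8983,33.3929,1.4445
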