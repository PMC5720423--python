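energy_keV,mu_pe,mu_incoh,mu_coh,mu_en
1,9300.43,0.00435579,1.50138,7870.65
1.12309,6392.29,0.00586263,1.47705,5463.47
1.26133,4393.5,0.0078346,1.44746,3792.51
1.41658,3019.7,0.010381,1.41181,2632.6
1.55804,2220.45,0.0129787,1.37748,1951.6
1.56116,2206.15,0.0130387,1.37671,1939.37
1.59095,2075.48,0.0136176,1.36929,1827.44
1.78678,1426.5,0.0176563,1.31923,1268.53
1.83706,1304.19,0.0187516,1.30609,1162.51
1.84074,1295.79,0.0188326,1.30512,1155.22
2.00671,980.452,0.0225905,1.26119,880.562
2.25372,673.876,0.0284773,1.19507,611.249
2.53112,463.163,0.0353192,1.12128,424.303
2.84268,318.338,0.0430495,1.04078,294.533
3.19258,218.797,0.0515245,0.955141,204.453
3.1997,217.229,0.0516931,0.953461,203.026
3.2061,215.83,0.0518446,0.951951,201.753
3.58555,150.382,0.0605265,0.866429,141.923
4,105.621,0.069245,0.782165,100.615
4.02689,103.359,0.0697807,0.77703,98.517
4.52256,71.0585,0.0789879,0.689394,68.366
5,51.4143,0.0866938,0.61678,49.8276
5.07923,48.8745,0.0878688,0.605757,47.417
5.70443,33.6318,0.096205,0.527912,32.8696
6.40658,23.1536,0.103862,0.457054,22.7732
7.19516,15.9473,0.110788,0.393744,15.7698
8,11.3488,0.116498,0.342526,11.268
8.08081,10.9889,0.117011,0.33799,10.9145
9.07546,7.57576,0.122616,0.289403,7.55033
10,5.55379,0.126916,0.253849,5.54713
10.1926,5.22513,0.127728,0.24736,5.2207
11.4471,3.60552,0.132473,0.211113,3.60839
12.8562,2.48909,0.136951,0.179861,2.49321
14.4386,1.71915,0.141221,0.152828,1.72237
15,1.52245,0.142583,0.144747,1.52526
16.2158,1.18792,0.145298,0.129336,1.18992
18.2118,0.821225,0.149148,0.108854,0.822422
20,0.609889,0.15204,0.0942571,0.610895
20.4535,0.567986,0.152697,0.0909995,0.569006
22,0.450711,0.154723,0.0810111,0.45193
22.9711,0.393019,0.155835,0.0755115,0.394454
24,0.342059,0.156889,0.0702408,0.34378
25,0.300563,0.157796,0.0656023,0.302605
25.7986,0.272076,0.158445,0.0622039,0.274395
26,0.265459,0.158598,0.0613864,0.26785
27,0.235568,0.159301,0.0575468,0.238331
27.202,0.230077,0.159431,0.0568132,0.232917
27.472,0.222997,0.1596,0.0558535,0.225941
28,0.209963,0.159912,0.0540431,0.213112
28.9741,0.188437,0.160425,0.0509193,0.191971
29,0.187906,0.160438,0.0508399,0.19145
30,0.168807,0.160887,0.0479062,0.172751
30.98,0.1525,0.161257,0.0452662,0.156836
31.71,0.141681,0.161492,0.043437,0.146309
32,0.137664,0.161577,0.0427406,0.142408
32.5405,0.130571,0.16172,0.0414863,0.135529
33,0.124915,0.16183,0.0404627,0.130056
34,0.113679,0.162029,0.0383616,0.119212
35,0.10374,0.16218,0.0364201,0.109659
35.492,0.0992694,0.162238,0.0355187,0.105376
36,0.0949166,0.162287,0.0346229,0.101216
36.5459,0.0905157,0.162328,0.0336978,0.0970194
38,0.0800361,0.162384,0.0314082,0.0870739
40,0.0680877,0.16235,0.0286248,0.075834
41.0443,0.0627774,0.162288,0.0273175,0.0708813
45,0.0469873,0.161836,0.0231032,0.0563705
46.0964,0.0435596,0.16166,0.0221083,0.053277
49.772,0.0342214,0.160952,0.0192038,0.0449995
50.742,0.0322069,0.160739,0.0185326,0.0432503
51.7703,0.0302388,0.160504,0.0178586,0.0415574
55,0.0250038,0.159709,0.0159643,0.0371468
57.5,0.0217469,0.159045,0.0146964,0.0344898
58.1427,0.0210013,0.158869,0.0143946,0.0338934
59.3,0.0197418,0.158547,0.0138741,0.0328976
63.121,0.0162302,0.157445,0.0123405,0.0302141
65.2994,0.0145925,0.156797,0.0115764,0.0290213
70,0.0117366,0.155363,0.0101499,0.0270655
73.3371,0.0101441,0.154326,0.00929019,0.0260669
80,0.00772758,0.152237,0.00786893,0.0247388
82.364,0.00705498,0.151494,0.00744181,0.0244244
92.5021,0.00490885,0.148338,0.00595256,0.0236728
93.614,0.0047291,0.147996,0.00581694,0.0236334
100,0.0038489,0.146055,0.00512082,0.0235174
103.888,0.00341716,0.144894,0.00475662,0.0235185
109.78,0.00287725,0.143167,0.0042749,0.0235924
116.676,0.00237972,0.141199,0.00379926,0.0237556
118.19,0.00228597,0.140774,0.00370558,0.0237994
130.52,0.00167788,0.137425,0.00305853,0.02422
131.037,0.00165733,0.137289,0.00303526,0.0242393
147.166,0.00115424,0.133201,0.00242757,0.024866
150,0.00108763,0.132514,0.0023405,0.0249771
165.281,0.000803857,0.128968,0.00194596,0.0255617
177.21,0.000646928,0.126372,0.00170699,0.0259898
185.625,0.000559839,0.124626,0.00156594,0.0262735
197.96,0.000458127,0.122183,0.00139164,0.0266607
208.473,0.000389895,0.120205,0.00126768,0.0269638
234.134,0.000271539,0.115735,0.00103512,0.0276053
261.08,0.000193373,0.111522,0.000864949,0.028146
262.954,0.000189111,0.111245,0.000855176,0.0281791
295.32,0.000131705,0.106758,0.000717142,0.0286717
307.74,0.000115836,0.10517,0.00067652,0.0288253
331.671,9.17246e-05,0.102295,0.000612204,0.0290743
372.496,6.38808e-05,0.0978762,0.000533094,0.029381
400,5.11623e-05,0.0951922,0.000494713,0.0295201
418.346,4.44892e-05,0.0935154,0.000473848,0.0295882
469.84,3.09841e-05,0.0892253,0.000429631,0.0296941
500,2.55229e-05,0.0869586,0.000410753,0.029709
527.672,2.15786e-05,0.0850158,0.000396627,0.0296984
592.622,1.50282e-05,0.0808947,0.000371925,0.0296014
662,1.06431e-05,0.0770521,0.000354107,0.029416
665.568,1.04663e-05,0.0768678,0.000353358,0.0294047
747.492,7.28915e-06,0.0729397,0.000339328,0.0291105
800,5.89918e-06,0.0706898,0.00033274,0.0288946
839.5,5.07647e-06,0.0691143,0.000328656,0.0287221
942.833,3.53546e-06,0.0653945,0.000320497,0.0282435
1000,2.94287e-06,0.0635495,0.000317129,0.0279679
1058.89,2.46224e-06,0.0617833,0.000314278,0.0276796
1170,1.80414e-06,0.0587676,0.000310179,0.0271312
1189.22,1.71481e-06,0.0582831,0.000309604,0.0270363
1250,1.46809e-06,0.0568149,0.000307998,0.0267374
1330,1.21001e-06,0.0550171,0.000306292,0.0263475
1335.6,1.19426e-06,0.0548965,0.000306187,0.0263204
1500,8.31733e-07,0.0516258,0.000303795,0.0255393
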