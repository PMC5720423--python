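energy_keV,mu_pe,mu_incoh,mu_coh,mu_en
1,12969,0.0031197,1.61992,11403.8
1.12309,8897.92,0.004223,1.5984,7885.39
1.26133,6104.78,0.00568258,1.57206,5452.49
1.41658,4188.43,0.00759201,1.54003,3770.22
1.55804,3075.35,0.00956697,1.50892,2786.05
1.56116,3055.45,0.00961292,1.50822,2768.4
1.59095,2873.64,0.0100568,1.50145,2606.98
1.78678,1971.58,0.0131884,1.45547,1802.64
1.83706,1801.76,0.0140481,1.4433,1650.45
1.84074,1790.1,0.0141118,1.4424,1639.99
2.00671,1352.68,0.017095,1.40136,1246.47
2.25372,928.061,0.0218669,1.33867,861.892
2.53112,636.734,0.0275604,1.26732,595.97
2.84268,436.857,0.0341805,1.18775,412.094
3.19258,299.723,0.0416668,1.10102,284.95
3.1997,297.564,0.0418182,1.0993,282.94
3.2061,295.639,0.0419543,1.09775,281.147
3.58555,205.637,0.0498863,1.00884,197.034
4,144.187,0.0581197,0.918993,139.175
4.02689,141.086,0.0586346,0.913443,136.243
4.52256,96.8493,0.0676501,0.817384,94.2115
5,70.0119,0.0754371,0.735833,68.4889
5.07923,66.5462,0.0766434,0.723297,65.1521
5.70443,45.7683,0.0853387,0.633582,45.0595
6.40658,31.5081,0.0935141,0.550166,31.166
7.19516,21.7116,0.101024,0.474332,21.5582
8,15.4642,0.107244,0.41221,15.397
8.08081,14.9754,0.107801,0.40668,14.9137
9.07546,10.339,0.113851,0.347212,10.3182
10,7.59158,0.118395,0.303497,7.58491
10.1926,7.14485,0.119239,0.295509,7.1397
11.4471,4.94223,0.124074,0.250909,4.94115
12.8562,3.4219,0.128475,0.212626,3.42038
14.4386,2.37151,0.132538,0.179826,2.36843
15,2.10276,0.133811,0.170104,2.0992
16.2158,1.64512,0.136324,0.151688,1.64079
18.2118,1.14232,0.139852,0.127478,1.13752
20,0.851678,0.142497,0.110397,0.847113
20.4535,0.793943,0.1431,0.106601,0.789504
22,0.632114,0.144971,0.0949887,0.628248
22.9711,0.55234,0.14601,0.0886068,0.548918
24,0.481763,0.147003,0.0824935,0.478856
25,0.4242,0.14787,0.0771119,0.421824
25.7986,0.384626,0.148496,0.0731663,0.382687
26,0.375426,0.148646,0.0722167,0.373599
27,0.33383,0.149336,0.0677525,0.33256
27.202,0.32618,0.149466,0.0668987,0.325024
27.472,0.316315,0.149634,0.0657813,0.315311
28,0.298141,0.149947,0.0636721,0.297432
28.9741,0.268092,0.150469,0.0600276,0.267926
29,0.26735,0.150482,0.0599349,0.267199
30,0.240647,0.150949,0.0565054,0.241047
30.98,0.217812,0.151343,0.053413,0.218743
31.71,0.202642,0.151599,0.0512669,0.203962
32,0.197006,0.151692,0.0504491,0.198479
32.5405,0.187045,0.151854,0.0489749,0.1888
33,0.179097,0.151979,0.0477708,0.181089
34,0.163292,0.152215,0.0452964,0.16579
35,0.149289,0.152404,0.0430067,0.15228
35.492,0.142984,0.152481,0.0419427,0.146212
36,0.13684,0.15255,0.0408846,0.140309
36.5459,0.130623,0.152612,0.0397913,0.134348
38,0.115799,0.152727,0.0370836,0.120185
40,0.0988555,0.152773,0.0337891,0.104104
41.0443,0.0913085,0.152752,0.0322412,0.0969874
45,0.068793,0.152448,0.0272528,0.0759836
46.0964,0.0638875,0.152311,0.0260761,0.0714666
49.772,0.0504827,0.151728,0.0226444,0.0592783
50.742,0.0475817,0.151547,0.0218521,0.0566781
51.7703,0.0447441,0.151345,0.021057,0.0541507
55,0.037176,0.15065,0.0188236,0.0475037
57.5,0.0324506,0.150062,0.0173299,0.0434408
58.1427,0.0313668,0.149905,0.0169745,0.0425208
59.3,0.0295338,0.149617,0.0163615,0.0409764
63.121,0.0244087,0.148625,0.0145563,0.0367502
65.2994,0.0220099,0.148037,0.013657,0.0348302
70,0.017811,0.146729,0.011978,0.0315908
73.3371,0.015459,0.145779,0.010966,0.0298658
80,0.0118716,0.143854,0.00929223,0.0274161
82.364,0.0108682,0.143168,0.00878899,0.0267841
92.5021,0.00764807,0.14024,0.00703312,0.0249966
93.614,0.00737679,0.139922,0.0068731,0.0248685
100,0.00604398,0.138114,0.00605144,0.0243117
103.888,0.00538715,0.13703,0.0056213,0.0240921
109.78,0.00456227,0.135416,0.00505205,0.0238846
116.676,0.00379776,0.133574,0.00448957,0.0237817
118.19,0.00365313,0.133177,0.00437873,0.0237744
130.52,0.00270966,0.130036,0.00361258,0.0238545
131.037,0.0026776,0.129908,0.00358502,0.0238619
147.166,0.00188784,0.126065,0.00286423,0.0241887
150,0.00178249,0.125419,0.00276083,0.0242584
165.281,0.00133102,0.122081,0.00229174,0.0246596
177.21,0.0010791,0.119635,0.00200708,0.0249801
185.625,0.00093843,0.117988,0.00183879,0.0252015
197.96,0.00077318,0.115683,0.0016305,0.0255126
208.473,0.000661638,0.113816,0.00148209,0.0257622
234.134,0.000466486,0.109596,0.00120284,0.0263045
261.08,0.000336052,0.105614,0.000997649,0.0267732
262.954,0.000328895,0.105352,0.000985837,0.0268022
295.32,0.000231887,0.10111,0.000818674,0.0272368
307.74,0.000204839,0.0996089,0.000769357,0.0273734
331.671,0.000163491,0.0968896,0.000691182,0.0275958
372.496,0.000115269,0.0927085,0.000594969,0.0278707
400,9.3018e-05,0.0901685,0.000548367,0.0279953
418.346,8.12703e-05,0.0885814,0.000523099,0.0280561
469.84,5.72994e-05,0.0845204,0.000469856,0.0281489
500,4.75117e-05,0.0823744,0.00044733,0.02816
527.672,4.03989e-05,0.080535,0.000430596,0.0281477
592.622,2.84831e-05,0.0766326,0.000401658,0.0280522
662,2.04096e-05,0.0729935,0.000381119,0.0278741
665.568,2.0082e-05,0.0728189,0.000380264,0.0278633
747.492,1.41587e-05,0.0690987,0.000364373,0.0275828
800,1.15414e-05,0.0669677,0.000357018,0.0273775
839.5,9.98259e-06,0.0654753,0.000352498,0.0272137
942.833,7.03821e-06,0.061952,0.000343553,0.0267594
1000,5.89512e-06,0.0602044,0.000339878,0.026498
1058.89,4.96227e-06,0.0585313,0.000336764,0.0262247
1170,3.67457e-06,0.0556748,0.000332249,0.0257048
1189.22,3.49864e-06,0.0552158,0.00033161,0.0256149
1250,3.01111e-06,0.053825,0.000329809,0.0253316
1330,2.49812e-06,0.052122,0.000327867,0.0249621
1335.6,2.46671e-06,0.0520078,0.000327746,0.0249364
1500,1.73915e-06,0.0489095,0.000324927,0.0241963
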