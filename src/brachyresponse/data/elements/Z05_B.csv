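energy_keV,mu_pe,mu_incoh,mu_coh,mu_en
1,2825.43,0.0107089,0.805769,2250.38
1.12309,1901.3,0.0139052,0.779616,1535.77
1.26133,1279.43,0.0178075,0.749149,1048.09
1.41658,860.955,0.0224495,0.71427,715.266
1.55804,622.191,0.0267965,0.682482,522.897
1.56116,617.959,0.0268928,0.681784,519.466
1.59095,579.356,0.0278127,0.675139,488.133
1.78678,389.862,0.0338161,0.632237,333.126
1.83706,354.635,0.0353315,0.621506,304.045
1.84074,352.223,0.0354417,0.620726,302.05
2.00671,262.347,0.0403157,0.586385,227.342
2.25372,176.539,0.0471173,0.538696,155.149
2.53112,118.797,0.0539988,0.49047,105.882
2.84268,79.9414,0.0607368,0.443034,72.259
3.19258,53.7944,0.0671357,0.397584,49.3133
3.1997,53.387,0.0672542,0.396737,48.9531
3.2061,53.0239,0.0673604,0.395979,48.6319
3.58555,36.1995,0.0730601,0.355067,33.6541
4,24.9228,0.078164,0.318278,23.4796
4.02689,24.3595,0.0784619,0.316136,22.9675
4.52256,16.4031,0.0833866,0.281139,15.6706
5,11.6645,0.0873448,0.254099,11.2561
5.07923,11.0588,0.0879458,0.250126,10.6872
5.70443,7.46478,0.0922731,0.222864,7.28547
6.40658,5.04486,0.0964893,0.198893,4.96448
7.19516,3.41356,0.100687,0.177635,3.38164
8,2.39172,0.104556,0.160107,2.38064
8.08081,2.31254,0.104926,0.158525,2.30272
9.07546,1.56854,0.109232,0.141102,1.56767
10,1.13503,0.112873,0.127594,1.13678
10.1926,1.0652,0.113591,0.125038,1.06718
11.4471,0.724246,0.117943,0.11013,0.726611
12.8562,0.493024,0.122192,0.0962862,0.49503
14.4386,0.336028,0.126228,0.0835041,0.337699
15,0.296334,0.127489,0.0795438,0.297955
16.2158,0.229302,0.129947,0.071836,0.230937
18.2118,0.156662,0.133288,0.0613445,0.158602
20,0.115308,0.135697,0.0537594,0.117714
20.4535,0.107163,0.136237,0.0520595,0.109705
22,0.0844816,0.137897,0.0468359,0.0875201
22.9711,0.0733926,0.138815,0.0439525,0.0767606
24,0.063641,0.139697,0.0411824,0.0673658
25,0.055734,0.140474,0.0387364,0.0598089
25.7986,0.050325,0.141044,0.0369375,0.0546796
26,0.049071,0.141181,0.0365036,0.0534961
27,0.0434184,0.141824,0.0344588,0.0481916
27.202,0.0423821,0.141947,0.0340666,0.0472253
27.472,0.0410473,0.142107,0.0335527,0.0459837
28,0.0385929,0.142408,0.0325804,0.0437107
28.9741,0.0345494,0.142924,0.0308928,0.0399982
29,0.0344497,0.142937,0.0308498,0.0399073
30,0.0308732,0.143415,0.0292509,0.036665
30.98,0.0278283,0.143836,0.0277987,0.0339417
31.71,0.025813,0.144122,0.0267839,0.0321619
32,0.0250659,0.144229,0.0263956,0.0315073
32.5405,0.0237477,0.144419,0.0256931,0.0303602
33,0.0226981,0.144571,0.0251169,0.0294546
34,0.0206167,0.144872,0.0239253,0.0276814
35,0.0187799,0.145136,0.0228128,0.026146
35.492,0.0179551,0.145252,0.0222925,0.0254671
36,0.017153,0.145363,0.0217727,0.0248138
36.5459,0.0163428,0.145472,0.0212333,0.0241618
38,0.0144177,0.145717,0.0198861,0.0226484
40,0.0122301,0.145949,0.0182245,0.0210053
41.0443,0.0112605,0.146027,0.017435,0.0203105
45,0.00838897,0.146085,0.0148532,0.0184237
46.0964,0.0077681,0.146043,0.0142362,0.0180612
49.772,0.00608189,0.145754,0.0124216,0.017199
50.742,0.00571921,0.145644,0.0119998,0.0170437
51.7703,0.00536532,0.145514,0.0115756,0.0169053
55,0.00442607,0.145029,0.0103797,0.0166157
57.5,0.00384342,0.144586,0.00957674,0.0165095
58.1427,0.00371024,0.144464,0.00938542,0.0164954
59.3,0.00348542,0.144237,0.00905511,0.0164814
63.121,0.00285988,0.14343,0.00808045,0.0165227
65.2994,0.00256881,0.142937,0.00759387,0.0165928
70,0.00206239,0.141816,0.00668329,0.0168235
73.3371,0.00178069,0.140984,0.00613285,0.0170329
80,0.00135429,0.13927,0.00521929,0.0175164
82.364,0.00123586,0.138651,0.00494371,0.0177001
92.5021,0.000858764,0.135979,0.00397835,0.0185118
93.614,0.000827239,0.135686,0.00389006,0.018601
100,0.000673012,0.134014,0.00343582,0.0191072
103.888,0.000597453,0.133006,0.00319743,0.019408
109.78,0.000503048,0.131498,0.00288133,0.0198501
116.676,0.000416094,0.129769,0.00256834,0.0203439
118.19,0.00039971,0.129395,0.00250659,0.0204487
130.52,0.000293422,0.126426,0.00207919,0.0212535
131.037,0.00028983,0.126305,0.00206379,0.0212854
147.166,0.00020188,0.12265,0.00166097,0.0222063
150,0.000190235,0.122033,0.00160315,0.0223541
165.281,0.000140619,0.118839,0.00134079,0.0230859
177.21,0.000113178,0.116492,0.00118154,0.0235873
185.625,9.79483e-05,0.114908,0.00108737,0.0239082
197.96,8.01597e-05,0.11269,0.000970749,0.0243345
208.473,6.82257e-05,0.110889,0.000887551,0.0246606
234.134,4.75225e-05,0.106812,0.000730475,0.0253336
261.08,3.38473e-05,0.102958,0.000614037,0.0258865
262.954,3.31017e-05,0.102704,0.000607287,0.0259201
295.32,2.3057e-05,0.0985913,0.000510825,0.0264151
307.74,2.02801e-05,0.0971345,0.000481895,0.0265682
331.671,1.60603e-05,0.0944943,0.000435334,0.0268155
372.496,1.11868e-05,0.0904316,0.000376205,0.0271192
400,8.96037e-06,0.0879619,0.00034641,0.0272573
418.346,7.79212e-06,0.0864182,0.000329789,0.0273253
469.84,5.42759e-06,0.0824664,0.000293269,0.0274339
500,4.47131e-06,0.0803772,0.000277006,0.0274521
527.672,3.78058e-06,0.078586,0.000264519,0.0274456
592.622,2.63336e-06,0.0747847,0.00024194,0.0273617
662,1.86523e-06,0.0712384,0.000225024,0.0271942
665.568,1.83426e-06,0.0710683,0.000224301,0.027184
747.492,1.27765e-06,0.0674416,0.000210638,0.0269151
800,1.03411e-06,0.0653636,0.000204177,0.0267168
839.5,8.89945e-07,0.0639083,0.000200184,0.0265582
942.833,6.1989e-07,0.0604716,0.000192321,0.0261173
1000,5.16029e-07,0.0587666,0.000189157,0.025863
1058.89,4.31783e-07,0.0571343,0.000186536,0.025597
1170,3.1642e-07,0.0543471,0.000182884,0.0250906
1189.22,3.00758e-07,0.0538992,0.000182384,0.025003
1250,2.57503e-07,0.052542,0.000181005,0.0247269
1330,2.12254e-07,0.0508801,0.000179565,0.0243667
1335.6,2.09492e-07,0.0507686,0.000179478,0.0243416
1500,1.45922e-07,0.047745,0.000177481,0.0236198
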