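energy_keV,mu_pe,mu_incoh,mu_coh,mu_en
1,717.096,0.0167421,0.410477,524.086
1.12309,474.492,0.0200472,0.392004,353.605
1.26133,313.964,0.0235275,0.372296,238.58
1.41658,207.745,0.0270859,0.351829,160.972
1.55804,148.073,0.0300063,0.334859,116.583
1.56116,147.023,0.0300675,0.334503,115.795
1.59095,137.462,0.0306449,0.331141,108.609
1.78678,90.9563,0.0341661,0.310757,73.2793
1.83706,82.4052,0.0350025,0.305979,66.7002
1.84074,81.8209,0.0350627,0.305637,66.2495
2.00671,60.1844,0.0376603,0.291105,49.4422
2.25372,39.8231,0.0411866,0.272454,33.3591
2.53112,26.3503,0.0448408,0.25488,22.5078
2.84268,17.4356,0.0487382,0.238281,15.1863
3.19258,11.5369,0.0529945,0.222411,10.2465
3.1997,11.4458,0.0530804,0.222111,10.1695
3.2061,11.3647,0.0531577,0.221842,10.1008
3.58555,7.63377,0.0577125,0.206951,6.91364
4,5.17299,0.0626508,0.192484,4.7721
4.02689,5.05116,0.0629699,0.191596,4.66496
4.52256,3.34494,0.0688064,0.176118,3.14621
5,2.34493,0.0743106,0.162554,2.23667
5.07923,2.21823,0.0752086,0.160414,2.12014
5.70443,1.47314,0.0820967,0.14452,1.4276
6.40658,0.979725,0.0893234,0.128608,0.96064
7.19516,0.652506,0.0966898,0.112967,0.646113
8,0.450702,0.103357,0.0992164,0.449682
8.08081,0.435197,0.103979,0.0979503,0.434499
9.07546,0.290675,0.110997,0.0839128,0.292307
10,0.207684,0.116545,0.0731383,0.21008
10.1926,0.194424,0.117596,0.0711333,0.196905
11.4471,0.130231,0.123669,0.0597694,0.133017
12.8562,0.0873569,0.129132,0.0498523,0.0903382
14.4386,0.0586816,0.1339,0.0413191,0.0619257
15,0.051506,0.135302,0.0387989,0.0548624
16.2158,0.0394755,0.1379,0.0340575,0.0431048
18.2118,0.0265934,0.141094,0.0279376,0.0307315
20,0.0193557,0.143095,0.02374,0.0239821
20.4535,0.0179408,0.143501,0.0228244,0.022693
22,0.0140226,0.144636,0.0200671,0.0192051
22.9711,0.0121207,0.145182,0.0185814,0.017572
24,0.0104569,0.145643,0.0171787,0.0161903
25,0.00911468,0.145995,0.0159608,0.0151189
25.7986,0.00820044,0.146215,0.0150777,0.014418
26,0.00798898,0.146263,0.0148664,0.01426
27,0.00703833,0.146461,0.0138794,0.0135718
27.202,0.00686453,0.146493,0.0136918,0.0134505
27.472,0.00664087,0.146532,0.0134469,0.0132967
28,0.00623033,0.146597,0.0129863,0.0130218
28.9741,0.00555605,0.146677,0.0121955,0.0125943
29,0.00553947,0.146679,0.0121754,0.0125843
30,0.0049455,0.146714,0.0114371,0.0122389
30.98,0.00444175,0.146708,0.0107759,0.0119743
31.71,0.00410941,0.146681,0.0103194,0.0118173
32,0.00398643,0.146665,0.0101459,0.0117632
32.5405,0.00376978,0.146628,0.00983387,0.0116741
33,0.00359759,0.14659,0.00957962,0.0116092
34,0.00325695,0.146487,0.00905877,0.011499
35,0.00295734,0.146358,0.00857867,0.0114254
35.492,0.00282315,0.146287,0.00835616,0.0114009
36,0.00269284,0.146207,0.00813524,0.0113827
36.5459,0.00256146,0.146116,0.00790733,0.0113707
38,0.00225017,0.145848,0.00734438,0.0113715
40,0.00189823,0.145424,0.00666221,0.0114355
41.0443,0.00174292,0.145182,0.00634275,0.0114914
45,0.00128583,0.144167,0.00531804,0.0118006
46.0964,0.00118766,0.143863,0.00507752,0.0119057
49.772,0.000922434,0.142795,0.00437928,0.0122959
50.742,0.000865695,0.142503,0.00421889,0.0124058
51.7703,0.000810446,0.14219,0.00405824,0.0125243
55,0.000664429,0.141188,0.00360908,0.0129063
57.5,0.000574359,0.140399,0.0033106,0.0132074
58.1427,0.000553832,0.140194,0.00323985,0.013285
59.3,0.000519238,0.139825,0.00311804,0.0134249
63.121,0.000423385,0.138602,0.00276124,0.0138845
65.2994,0.000379011,0.137903,0.00258468,0.0141434
70,0.00030221,0.1364,0.00225733,0.0146902
73.3371,0.000259745,0.135341,0.00206157,0.0150665
80,0.000195893,0.13326,0.00174066,0.0157847
82.364,0.000178264,0.132535,0.00164492,0.0160284
92.5021,0.000122518,0.129507,0.00131383,0.0170084
93.614,0.000117889,0.129184,0.0012839,0.0171095
100,9.53239e-05,0.127362,0.00113091,0.0176674
103.888,8.43253e-05,0.126283,0.0010513,0.0179884
109.78,7.06441e-05,0.124688,0.000946491,0.0184495
116.676,5.81107e-05,0.122886,0.000843569,0.0189527
118.19,5.57571e-05,0.122499,0.000823366,0.0190583
130.52,4.05634e-05,0.119464,0.000684454,0.0198562
131.037,4.00525e-05,0.119341,0.000679481,0.0198874
147.166,2.7606e-05,0.115672,0.000550038,0.0207798
150,2.59686e-05,0.11506,0.000531563,0.0209215
165.281,1.90273e-05,0.111906,0.000448012,0.0216187
177.21,1.52176e-05,0.109607,0.000397474,0.0220927
185.625,1.31145e-05,0.108065,0.000367626,0.0223947
197.96,1.06702e-05,0.105913,0.000330671,0.0227946
208.473,9.03908e-06,0.104174,0.000304296,0.0230996
234.134,6.23014e-06,0.100255,0.000254423,0.0237268
261.08,4.39367e-06,0.0965714,0.000217361,0.0242402
262.954,4.29409e-06,0.0963297,0.00021521,0.0242713
295.32,2.95968e-06,0.0924162,0.000184498,0.0247295
307.74,2.59351e-06,0.0910336,0.000175313,0.0248708
331.671,2.03995e-06,0.0885315,0.000160606,0.0250987
372.496,1.40602e-06,0.0846897,0.000142216,0.0253777
400,1.11893e-06,0.0823586,0.000133196,0.0255039
418.346,9.69094e-07,0.0809029,0.000128286,0.0255657
469.84,6.67943e-07,0.0771807,0.000117971,0.0256629
500,5.47159e-07,0.0752151,0.000113682,0.0256778
527.672,4.60377e-07,0.0735308,0.000110569,0.0256699
592.622,3.17312e-07,0.0699593,0.000105464,0.025588
662,2.22507e-07,0.0666305,0.000102229,0.0254286
665.568,2.18706e-07,0.0664708,0.000102105,0.0254189
747.492,1.50742e-07,0.0630692,0.000100002,0.0251649
800,1.21258e-07,0.0611213,9.91869e-05,0.0249782
839.5,1.03898e-07,0.0597573,9.87469e-05,0.0248291
942.833,7.16113e-08,0.0565378,9.80335e-05,0.024415
1000,5.92952e-08,0.0549411,9.78086e-05,0.0241766
1058.89,4.93577e-08,0.0534128,9.76526e-05,0.0239272
1170,3.58441e-08,0.0508037,9.74871e-05,0.0234528
1189.22,3.40195e-08,0.0503845,9.74697e-05,0.0233707
1250,2.89954e-08,0.0491144,9.74287e-05,0.0231121
1330,2.37659e-08,0.0475594,9.73974e-05,0.0227749
1335.6,2.34478e-08,0.047455,9.73959e-05,0.0227515
1500,1.61613e-08,0.0446264,9.73727e-05,0.0220759
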