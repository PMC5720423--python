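energy_keV,mu_pe,mu_incoh,mu_coh,mu_en
1,5597.68,0.00832886,1.07872,4766.85
1.12309,3752.77,0.0109888,1.05099,3230.21
1.26133,2515.91,0.0143403,1.01806,2188.92
1.41658,1686.7,0.0184781,0.979517,1483.3
1.55804,1215.21,0.0225059,0.943541,1078.1
1.56116,1206.87,0.0225969,0.942742,1070.9
1.59095,1130.79,0.0234694,0.93511,1005.14
1.78678,758.099,0.0293356,0.884914,681.125
1.83706,688.984,0.0308648,0.872097,620.616
1.84074,684.253,0.0309768,0.871161,616.469
2.00671,508.241,0.0360372,0.829383,461.558
2.25372,340.732,0.0434643,0.769406,312.77
2.53112,228.432,0.0514387,0.706284,211.946
2.84268,153.144,0.0597255,0.641627,143.623
3.19258,102.67,0.0680576,0.577186,97.3251
3.1997,101.885,0.0682162,0.575963,96.601
3.2061,101.186,0.0683585,0.574865,95.9556
3.58555,68.8316,0.0761723,0.514654,65.9517
4,47.2231,0.0834266,0.458795,45.707
4.02689,46.1459,0.0838556,0.455493,44.6919
4.52256,30.9734,0.09098,0.400802,30.296
5,21.9803,0.0966646,0.357652,21.6586
5.07923,20.8335,0.0975168,0.351255,20.5502
5.70443,14.0427,0.103519,0.30709,13.9485
6.40658,9.48549,0.109092,0.268159,9.47368
7.19516,6.42074,0.114363,0.234032,6.43878
8,4.50386,0.119024,0.206559,4.52767
8.08081,4.3554,0.119462,0.20412,4.37919
9.07546,2.96066,0.124495,0.177789,2.98066
10,2.14781,0.128704,0.158093,2.16254
10.1926,2.01682,0.129534,0.154437,2.03049
11.4471,1.37677,0.134603,0.13355,1.38459
12.8562,0.941836,0.139673,0.114744,0.945336
14.4386,0.645663,0.144651,0.0977761,0.646502
15,0.570593,0.146244,0.0925793,0.570883
16.2158,0.443562,0.149395,0.0825313,0.443159
18.2118,0.305365,0.153726,0.0689838,0.304799
20,0.226293,0.156798,0.0592973,0.226157
20.4535,0.21067,0.157468,0.0571434,0.210693
22,0.167049,0.159453,0.0505781,0.167705
22.9711,0.145648,0.160486,0.0469972,0.146747
24,0.126776,0.161422,0.0435939,0.128366
25,0.11143,0.162192,0.0406244,0.113508
25.7986,0.100907,0.162719,0.0384647,0.103375
26,0.098464,0.16284,0.0379472,0.10103
27,0.0874334,0.16338,0.0355272,0.0904859
27.202,0.0854079,0.163478,0.0350667,0.0885579
27.472,0.0827971,0.163601,0.0344652,0.086077
28,0.0779913,0.163825,0.0333333,0.0815236
28.9741,0.0700579,0.164177,0.031388,0.0740493
29,0.0698622,0.164186,0.0313387,0.0738656
30,0.0628258,0.164472,0.0295201,0.0672901
30.98,0.0568194,0.164688,0.0278891,0.0617242
31.71,0.0528347,0.164813,0.0267614,0.0580605
32,0.0513555,0.164855,0.0263326,0.0567069
32.5405,0.0487428,0.164921,0.0255606,0.0543258
33,0.0466598,0.164966,0.0249309,0.0524368
34,0.042521,0.165032,0.0236391,0.0487116
35,0.038859,0.165057,0.0224455,0.0454513
35.492,0.0372115,0.165055,0.0218913,0.0439971
36,0.035607,0.165045,0.0213404,0.0425893
36.5459,0.0339845,0.165025,0.0207712,0.0411749
38,0.0301191,0.164928,0.0193613,0.0378476
40,0.0257075,0.164706,0.0176442,0.03414
41.0443,0.0237448,0.164555,0.0168363,0.0325291
45,0.0178978,0.16381,0.0142254,0.0279259
46.0964,0.0166255,0.163564,0.0136078,0.0269757
49.772,0.0131515,0.162644,0.0118031,0.0245181
50.742,0.0124002,0.162381,0.0113859,0.0240199
51.7703,0.0116654,0.162094,0.010967,0.0235473
55,0.00970608,0.161151,0.00978988,0.0223722
57.5,0.00848293,0.160386,0.0090027,0.0217188
58.1427,0.00820237,0.160185,0.00881549,0.0215798
59.3,0.00772788,0.15982,0.00849263,0.0213556
63.121,0.00640092,0.158589,0.00754272,0.0208146
65.2994,0.0057796,0.157874,0.00707022,0.0206158
70,0.00469129,0.156312,0.00618974,0.0203832
73.3371,0.00408106,0.155196,0.00566032,0.0203385
80,0.00314893,0.152971,0.00478738,0.0204452
82.364,0.0028878,0.152186,0.00452567,0.0205268
92.5021,0.00204775,0.14888,0.00361573,0.0210251
93.614,0.0019768,0.148524,0.00353308,0.0210892
100,0.00162764,0.146511,0.00310951,0.0214767
103.888,0.00145514,0.145311,0.00288837,0.0217223
109.78,0.001238,0.143533,0.00259642,0.0220993
116.676,0.00103594,0.141513,0.00230885,0.0225382
118.19,0.000997589,0.141079,0.0022523,0.0226335
130.52,0.000746269,0.137659,0.00186266,0.0233833
131.037,0.000737688,0.13752,0.00184869,0.0234136
147.166,0.000525305,0.133363,0.0014847,0.0243047
150,0.000496803,0.132667,0.00143275,0.0244502
165.281,0.000374068,0.129076,0.00119807,0.0251786
177.21,0.000305087,0.126453,0.00105666,0.0256842
185.625,0.000266373,0.12469,0.0009735,0.0260102
197.96,0.00022068,0.122228,0.000871098,0.0264457
208.473,0.000189683,0.120235,0.000798531,0.0267806
234.134,0.000135073,0.115739,0.000662997,0.0274756
261.08,9.82178e-05,0.111506,0.000564253,0.02805
262.954,9.61849e-05,0.111229,0.000558587,0.0280849
295.32,6.84929e-05,0.106726,0.000478533,0.0286011
307.74,6.07177e-05,0.105134,0.000454909,0.0287608
331.671,4.87736e-05,0.102253,0.000417353,0.0290191
372.496,3.47315e-05,0.0978258,0.00037065,0.0293358
400,2.81987e-05,0.0951384,0.000347622,0.0294793
418.346,2.47322e-05,0.0934598,0.000334946,0.0295496
469.84,1.76117e-05,0.0891667,0.000307559,0.0296599
500,1.46814e-05,0.0868991,0.000295579,0.0296764
527.672,1.25412e-05,0.0849558,0.000286471,0.0296669
592.622,8.93058e-06,0.0808342,0.000270188,0.0295718
662,6.46021e-06,0.076992,0.000258123,0.0293875
665.568,6.35944e-06,0.0768077,0.00025761,0.0293763
747.492,4.52854e-06,0.0728806,0.000247934,0.029083
800,3.71294e-06,0.0706315,0.000243381,0.0288675
839.5,3.22476e-06,0.0690565,0.000240578,0.0286952
942.833,2.29634e-06,0.0653384,0.000235107,0.0282171
1000,1.93311e-06,0.0634942,0.000232939,0.0279417
1058.89,1.63521e-06,0.0617289,0.000231175,0.0276537
1170,1.22128e-06,0.0587149,0.000228804,0.0271056
1189.22,1.16443e-06,0.0582306,0.000228493,0.0270109
1250,1.00646e-06,0.0567632,0.000227659,0.0267121
1330,8.39445e-07,0.0549665,0.000226844,0.0263225
1335.6,8.29188e-07,0.0548459,0.000226797,0.0262954
1500,5.90462e-07,0.0515774,0.000225834,0.0255148
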