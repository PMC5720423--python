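energy_keV,mu_pe,mu_incoh,mu_coh,mu_en
1,12071.4,0.00394262,3.04122,11971
1.12309,8227,0.00526426,2.99188,8162.64
1.26133,5606.95,0.00696722,2.93227,5565.86
1.41658,3821.3,0.00912528,2.86097,3795.19
1.55804,2790.49,0.0112829,2.79291,2772.55
1.56116,2772.11,0.0113323,2.79138,2754.32
1.59095,2604.33,0.0118071,2.77674,2587.82
1.78678,1774.93,0.0150656,2.67866,1764.56
1.83706,1619.46,0.0159334,2.65311,1610.19
1.84074,1608.8,0.0159973,2.65123,1599.6
2.00671,1209.67,0.0189248,2.56638,1203.2
2.25372,824.424,0.0233684,2.44032,820.423
2.53112,561.87,0.0283325,2.30188,559.422
2.84268,382.931,0.0337057,2.15346,381.453
3.19258,260.979,0.0393411,1.99833,260.101
3.1997,259.066,0.0394508,1.99531,258.197
3.2061,2444.92,0.0395493,1.9926,2198.9
3.58555,1689.72,0.0450777,1.84039,1537.82
4,1177.36,0.0504462,1.69263,1082.65
4.02689,1151.6,0.0507717,1.68368,1059.59
4.52256,786.311,0.0563318,1.53195,730.507
5,566.891,0.0610177,1.4071,530.585
5.07923,538.688,0.0617437,1.38818,504.74
5.70443,370.279,0.0670714,1.25429,349.563
6.40658,255.37,0.0724285,1.13092,242.687
7.19516,176.71,0.0779338,1.01751,168.918
8,126.608,0.0831663,0.921388,121.599
8.08081,122.688,0.0836738,0.912596,117.883
9.07546,85.4654,0.0896798,0.814442,82.4911
10,63.3415,0.0948792,0.736591,61.3426
10.1926,59.735,0.0959158,0.721686,57.8858
11.4471,41.8907,0.102271,0.633704,40.7355
12.8562,29.4751,0.108566,0.550647,28.7499
14.4386,20.8085,0.114573,0.473239,20.3509
15,18.5725,0.116445,0.449201,18.1786
16.2158,14.7393,0.120064,0.402461,14.449
18.2118,10.4752,0.124861,0.33919,10.2903
20,7.97174,0.128167,0.293944,7.84292
20.4535,7.46961,0.128882,0.283885,7.35148
22,6.05094,0.131014,0.253209,5.96181
22.9711,5.34419,0.132143,0.236448,5.26884
24,4.71379,0.13319,0.220478,4.65032
25,4.19537,0.134082,0.206497,4.14136
25.7986,3.83633,0.134717,0.196292,3.78871
26,3.75252,0.134868,0.193842,3.70638
27,3.3718,0.13556,0.18235,3.33224
27.202,3.30144,0.13569,0.180157,3.26308
27.472,3.21053,0.135858,0.17729,3.17372
28,3.04252,0.136171,0.171882,3.00854
28.9741,2.76311,0.136697,0.162554,2.73376
29,2.75618,0.13671,0.162317,2.72694
30,2.5059,0.137185,0.153552,2.48073
30.98,2.29021,0.137596,0.145651,2.2685
31.71,2.14597,0.137869,0.140165,2.12654
32,2.09217,0.137971,0.138074,2.07359
32.5405,1.99678,0.13815,0.134301,1.9797
33,1.92039,0.138292,0.131217,1.90449
34,1.76763,0.138572,0.124869,1.7541
35,1.63127,0.138814,0.118977,1.61984
35.492,1.56953,0.13892,0.116232,1.55904
36,1.50915,0.139021,0.113497,1.49958
36.5459,1.44781,0.13912,0.110666,1.43918
38,1.3005,0.139342,0.103624,1.29411
40,1.13004,0.139556,0.0949905,1.12625
41.0443,1.05328,0.139631,0.0909048,1.05066
45,0.820457,0.139715,0.0775883,0.821457
46.0964,0.768818,0.139691,0.0744107,0.77064
49.772,0.625551,0.139488,0.0650577,0.629718
50.742,0.594059,0.139407,0.0628801,0.59876
51.7703,0.563058,0.139309,0.0606874,0.568294
55,0.479302,0.138936,0.0544912,0.486033
57.5,0.426072,0.138587,0.0503166,0.433806
58.1427,0.413745,0.13849,0.0493199,0.421718
59.3,0.392786,0.138309,0.0475975,0.401174
63.121,0.333351,0.137653,0.0425021,0.342979
65.2994,0.305043,0.137246,0.0399514,0.315301
70,0.254559,0.136303,0.0351676,0.26603
73.3371,0.225652,0.135592,0.0322705,0.237883
80,0.180431,0.134101,0.0274571,0.193991
82.364,0.167481,0.133555,0.0260044,0.181463
92.5021,0.124722,0.131166,0.0209151,0.140288
93.614,0.121017,0.130901,0.0204496,0.136739
100,0.102518,0.129382,0.0180546,0.119072
103.888,0.0931897,0.128459,0.0167973,0.110207
109.78,0.0812319,0.127073,0.0151294,0.0988991
116.676,0.0698323,0.125473,0.0134763,0.0881897
118.19,0.0676324,0.125126,0.0131499,0.0861325
130.52,0.0528668,0.122359,0.0108871,0.0724254
131.037,0.0523505,0.122245,0.0108054,0.0719498
147.166,0.0392451,0.118813,0.00866303,0.0599904
150,0.0374305,0.118232,0.00835442,0.0583549
165.281,0.0294204,0.115213,0.00694932,0.0512148
177.21,0.0247471,0.112986,0.0060918,0.0471239
185.625,0.0220553,0.11148,0.00558268,0.0447999
197.96,0.0188001,0.109366,0.0049498,0.0420279
208.473,0.016534,0.107647,0.00449655,0.0401279
234.134,0.0123949,0.103745,0.0036366,0.0367356
261.08,0.00945833,0.100046,0.00299568,0.0344055
262.954,0.00929193,0.0998022,0.00295844,0.0342757
295.32,0.00696579,0.0958442,0.00242574,0.0324883
307.74,0.00628873,0.0944403,0.00226589,0.0319774
331.671,0.00522197,0.0918932,0.0020088,0.0311791
372.496,0.0039147,0.0879682,0.00168339,0.0302029
400,0.00328023,0.0855794,0.00152037,0.0297208
418.346,0.0029347,0.0840852,0.00142986,0.0294516
469.84,0.00220002,0.0802572,0.00123235,0.0288448
500,0.00188521,0.0782318,0.00114507,0.0285576
527.672,0.00164927,0.0764945,0.00107834,0.0283229
592.622,0.00123639,0.0728053,0.000958269,0.0278421
662,0.000939321,0.0693613,0.000868861,0.0273924
665.568,0.000926872,0.069196,0.000865057,0.0273704
747.492,0.000694839,0.0656718,0.000793405,0.0268851
800,0.000587085,0.0636518,0.000759819,0.0265883
839.5,0.000520893,0.0622367,0.000739214,0.0263703
942.833,0.000390492,0.0588941,0.000699169,0.0258156
1000,0.000337408,0.0572353,0.000683356,0.0255171
1058.89,0.000292737,0.055647,0.000670458,0.0252152
1170,0.000228511,0.0529344,0.00065292,0.0246605
1189.22,0.000219453,0.0524985,0.000650574,0.0245665
1250,0.000193914,0.0511774,0.000644171,0.0242731
1330,0.00016624,0.0495596,0.000637634,0.0238958
1335.6,0.000164515,0.049451,0.000637241,0.0238697
1500,0.00012333,0.0465072,0.000628474,0.0231272
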