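energy_keV,mu_pe,mu_incoh,mu_coh,mu_en
1,9.49741,0.0239479,0.358503,9.87966
1.12309,6.23166,0.0317965,0.349441,6.61277
1.26133,4.08886,0.0417945,0.338583,4.46915
1.41658,2.68288,0.0542858,0.325728,3.06283
1.55804,1.89912,0.0665804,0.313591,2.27925
1.56116,1.88538,0.0668594,0.31332,2.26552
1.59095,1.76036,0.0695387,0.310727,2.14058
1.78678,1.15505,0.0876738,0.293517,1.53621
1.83706,1.04435,0.0924307,0.289079,1.42584
1.84074,1.0368,0.0927796,0.288755,1.41831
2.00671,0.757875,0.108589,0.274164,1.14061
2.25372,0.497275,0.131904,0.252895,0.882057
2.53112,0.326284,0.156952,0.230117,0.713339
2.84268,0.214089,0.182836,0.206406,0.603319
3.19258,0.140473,0.208553,0.182461,0.531476
3.1997,0.139342,0.209038,0.182004,0.530373
3.2061,0.138334,0.209473,0.181594,0.52939
3.58555,0.0921704,0.233146,0.159026,0.484332
4,0.0619659,0.254602,0.138032,0.4137
4.02689,0.0604766,0.255851,0.136792,0.403911
4.52256,0.0395906,0.276176,0.116308,0.266787
5,0.0273578,0.291656,0.100286,0.186592
5.07923,0.0258117,0.293904,0.0979265,0.17646
5.70443,0.0167594,0.309043,0.0817933,0.117153
6.40658,0.0108372,0.321743,0.0678813,0.0783784
7.19516,0.00697903,0.332226,0.0560415,0.0531736
8,0.00465224,0.340067,0.0468551,0.038067
8.08081,0.00447601,0.340731,0.0460583,0.0369299
9.07546,0.00285894,0.347489,0.0376953,0.0266017
10,0.00195947,0.351949,0.0317848,0.0210302
10.1926,0.0018186,0.352709,0.0307269,0.0201817
11.4471,0.0011521,0.356577,0.0249507,0.0163499
12.8562,0.000726872,0.359256,0.0201885,0.0142406
14.4386,0.000456715,0.360885,0.0162829,0.0132881
15,0.000391689,0.361212,0.0151625,0.013161
16.2158,0.000285792,0.361585,0.0130952,0.0131238
18.2118,0.000178104,0.361455,0.0105051,0.0135085
20,0.000121246,0.360804,0.00877981,0.0141117
20.4535,0.000110539,0.360581,0.00840912,0.0142876
22,8.17583e-05,0.359681,0.00730553,0.0149321
22.9711,6.83245e-05,0.359028,0.0067191,0.0153614
24,5.69176e-05,0.358277,0.006171,0.0158292
25,4.79856e-05,0.357499,0.00569966,0.0162921
25.7986,4.20586e-05,0.35685,0.0053607,0.0166654
26,4.07075e-05,0.356683,0.00527995,0.0167598
27,3.47331e-05,0.355835,0.00490466,0.0172298
27.202,3.36595e-05,0.35566,0.00483369,0.0173249
27.472,3.22869e-05,0.355425,0.00474119,0.0174519
28,2.97948e-05,0.354961,0.00456776,0.0177002
28.9741,2.57841e-05,0.354089,0.00427171,0.0181575
29,2.56868e-05,0.354065,0.00426424,0.0181696
30,2.22489e-05,0.353153,0.00398983,0.018637
30.98,1.94089e-05,0.352244,0.00374571,0.0190921
31.71,1.7577e-05,0.351561,0.00357807,0.0194289
32,1.69081e-05,0.351288,0.00351457,0.0195621
32.5405,1.57422e-05,0.350777,0.00340062,0.0198096
33,1.48273e-05,0.35034,0.00330804,0.0200189
34,1.305e-05,0.349386,0.00311912,0.0204712
35,1.15254e-05,0.348427,0.00294588,0.0209189
35.492,1.08551e-05,0.347954,0.00286588,0.0211373
36,1.0212e-05,0.347464,0.00278664,0.0213616
36.5459,9.57192e-06,0.346937,0.00270509,0.0216012
38,8.0905e-06,0.345532,0.00250449,0.0222319
40,6.48142e-06,0.343598,0.00226303,0.0230813
41.0443,5.79629e-06,0.34259,0.00215057,0.0235164
45,3.88339e-06,0.338794,0.00179248,0.0251125
46.0964,3.49559e-06,0.337751,0.00170902,0.0255406
49.772,2.49684e-06,0.334289,0.00146799,0.0269311
50.742,2.29352e-06,0.333385,0.00141289,0.0272869
51.7703,2.09946e-06,0.332433,0.0013578,0.0276592
55,1.60685e-06,0.329475,0.00120431,0.0287959
57.5,1.31936e-06,0.327224,0.00110274,0.0296431
58.1427,1.25578e-06,0.32665,0.00107871,0.0298565
59.3,1.15038e-06,0.325624,0.0010374,0.0302361
63.121,8.70722e-07,0.322286,0.000916698,0.0314495
65.2994,7.48062e-07,0.320419,0.000857151,0.0321148
70,5.47477e-07,0.316481,0.000747069,0.0334883
73.3371,4.43793e-07,0.313758,0.000681441,0.0344145
80,2.99325e-07,0.308498,0.000574188,0.0361513
82.364,2.62205e-07,0.306688,0.000542273,0.0367337
92.5021,1.54283e-07,0.299236,0.000432236,0.0390489
93.614,1.46053e-07,0.298448,0.000422318,0.039286
100,1.07815e-07,0.294033,0.00037171,0.0405887
103.888,9.041e-08,0.291432,0.000345447,0.0413352
109.78,7.00316e-08,0.287611,0.000310964,0.0424042
116.676,5.27912e-08,0.283314,0.000277241,0.0435672
118.19,4.97255e-08,0.282394,0.000270642,0.0438107
130.52,3.13802e-08,0.275211,0.000225534,0.0456478
131.037,3.08099e-08,0.274921,0.00022393,0.0457195
147.166,1.79812e-08,0.266296,0.000182593,0.0477679
150,1.64586e-08,0.26486,0.00017678,0.0480929
165.281,1.04941e-08,0.257486,0.000150915,0.0496896
177.21,7.59529e-09,0.252127,0.000135747,0.0507739
185.625,6.12457e-09,0.248538,0.000127036,0.0514644
197.96,4.54421e-09,0.243537,0.000116594,0.0523783
208.473,3.57441e-09,0.239501,0.000109441,0.053075
234.134,2.08609e-09,0.23042,9.68561e-05,0.0545071
261.08,1.25854e-09,0.221899,8.86255e-05,0.0556786
262.954,1.21748e-09,0.221341,8.81861e-05,0.0557495
295.32,7.10543e-10,0.212302,8.24757e-05,0.0567941
307.74,5.86942e-10,0.209112,8.10016e-05,0.0571161
331.671,4.14686e-10,0.203341,7.89045e-05,0.0576353
372.496,2.42018e-10,0.194488,7.67978e-05,0.05827
400,1.7391e-10,0.18912,7.59986e-05,0.0585566
418.346,1.41246e-10,0.185769,7.56332e-05,0.0586968
469.84,8.24338e-11,0.177204,7.50317e-05,0.0589159
500,6.17673e-11,0.172683,7.48486e-05,0.0589483
527.672,4.81099e-11,0.168811,7.474e-05,0.0589288
592.622,2.80778e-11,0.160601,7.46054e-05,0.0587381
662,1.68004e-11,0.152953,7.45482e-05,0.0583704
665.568,1.63867e-11,0.152586,7.45464e-05,0.058348
747.492,9.56357e-12,0.144772,7.4523e-05,0.0577636
800,6.97984e-12,0.140299,7.45174e-05,0.0573344
839.5,5.58147e-12,0.137167,7.45154e-05,0.0569917
942.833,3.25745e-12,0.129774,7.45135e-05,0.0560407
1000,2.47902e-12,0.126108,7.45133e-05,0.0554931
1058.89,1.90111e-12,0.1226,7.45132e-05,0.0549205
1170,1.19665e-12,0.11661,7.45132e-05,0.0538314
1189.22,1.10952e-12,0.115648,7.45132e-05,0.053643
1250,8.80469e-13,0.112733,7.45132e-05,0.0530495
1330,6.60286e-13,0.109163,7.45132e-05,0.0522754
1335.6,6.47535e-13,0.108924,7.45132e-05,0.0522215
1500,3.77913e-13,0.102431,7.45132e-05,0.050671
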