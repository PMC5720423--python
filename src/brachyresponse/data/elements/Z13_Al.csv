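energy_keV,mu_pe,mu_incoh,mu_coh,mu_en
1,2332.91,0.00714904,2.25642,2194.53
1.12309,1649.5,0.00906437,2.20403,1557.01
1.26133,1166.29,0.0113103,2.14388,1104.69
1.41658,824.635,0.0138765,2.07607,783.775
1.55804,620.618,0.0162027,2.01516,591.535
1.56116,6786.15,0.0162536,2.01383,6277.5
1.59095,6413.7,0.0167386,2.00119,5939.68
1.78678,4534.85,0.0198672,1.92027,4227.96
1.83706,4174.18,0.020652,1.90018,3897.73
1.84074,4149.33,0.0207091,1.89873,3874.95
2.00671,3206.4,0.0232417,1.83471,3008.43
2.25372,2267.11,0.0268608,1.74602,2139.97
2.53112,1602.97,0.0307473,1.65557,1521.77
2.84268,1133.39,0.0349477,1.56433,1081.89
3.19258,801.375,0.0395304,1.47273,768.982
3.1997,796.062,0.0396226,1.47097,763.959
3.2061,791.321,0.0397055,1.46939,759.477
3.58555,566.617,0.0445831,1.38079,546.466
4,408.727,0.0498618,1.29357,396.006
4.02689,400.63,0.0502032,1.28821,388.268
4.52256,283.132,0.0564748,1.19455,275.645
5,209.579,0.0624546,1.11239,204.768
5.07923,199.92,0.0634378,1.0994,195.435
5.70443,141.042,0.0710583,1.00259,138.386
6.40658,99.4179,0.0792087,0.904527,97.8659
7.19516,70.0171,0.0876686,0.806359,69.1229
8,50.7922,0.0954251,0.718194,50.2588
8.08081,49.2683,0.096153,0.709977,48.7607
9.07546,34.6381,0.104367,0.617672,34.3544
10,25.7865,0.110847,0.545281,25.6139
10.1926,24.3313,0.11207,0.531661,24.1749
11.4471,17.0765,0.119125,0.453615,16.9913
12.8562,11.9745,0.12549,0.384372,11.9282
14.4386,8.38958,0.131177,0.323948,8.36424
15,7.46249,0.132901,0.305929,7.44163
16.2158,5.87281,0.136203,0.27176,5.85869
18.2118,4.10748,0.140566,0.226953,4.09948
20,3.07625,0.143599,0.195581,3.07126
20.4535,2.87031,0.144261,0.188653,2.86589
22,2.2909,0.146243,0.167578,2.28807
22.9711,2.00404,0.147298,0.156085,2.00201
24,1.74951,0.148279,0.14514,1.74823
25,1.54138,0.149114,0.135562,1.54077
25.7986,1.398,0.149706,0.128574,1.39788
26,1.36463,0.149846,0.126896,1.36463
27,1.21361,0.150488,0.119031,1.21418
27.202,1.18581,0.150607,0.11753,1.18649
27.472,1.14994,0.150762,0.115569,1.15077
28,1.08382,0.151048,0.111871,1.08493
28.9741,0.974385,0.151525,0.105498,0.975996
29,0.97168,0.151536,0.105336,0.973305
30,0.874311,0.15196,0.0993559,0.876431
30.98,0.790962,0.152318,0.0939742,0.79355
31.71,0.735549,0.152551,0.0902436,0.738478
32,0.714954,0.152637,0.0888227,0.718014
32.5405,0.678545,0.152785,0.0862622,0.68185
33,0.649488,0.152901,0.0841713,0.652997
34,0.591676,0.153121,0.0798743,0.595621
35,0.540439,0.153301,0.0758966,0.544808
35.492,0.517362,0.153376,0.0740472,0.521936
36,0.494874,0.153445,0.0722072,0.499656
36.5459,0.472118,0.153509,0.0703049,0.47712
38,0.417848,0.153633,0.0655872,0.423422
40,0.355825,0.153707,0.0598313,0.362151
41.0443,0.328206,0.153706,0.0571199,0.33491
45,0.245878,0.153496,0.0483453,0.253926
46.0964,0.227964,0.153389,0.0462671,0.236362
49.772,0.179082,0.152903,0.0401893,0.188588
50.742,0.168522,0.152748,0.0387831,0.178305
51.7703,0.158201,0.152571,0.0373707,0.16827
55,0.130722,0.151954,0.0333999,0.141648
57.5,0.113611,0.151421,0.0307422,0.12516
58.1427,0.109692,0.151277,0.0301099,0.121395
59.3,0.103071,0.151011,0.0290191,0.115048
63.121,0.0846055,0.150088,0.0258076,0.0974386
65.2994,0.0759917,0.149534,0.0242088,0.0892841
70,0.0609718,0.148291,0.0212265,0.0751912
73.3371,0.0525994,0.147379,0.019431,0.0674286
80,0.0399056,0.145516,0.0164657,0.055849
82.364,0.0363763,0.144848,0.0155753,0.0526852
92.5021,0.0251351,0.14198,0.0124724,0.042862
93.614,0.0241955,0.141667,0.0121899,0.0420647
100,0.0196012,0.139884,0.0107402,0.0382435
103.888,0.0173527,0.138812,0.00998162,0.0364316
109.78,0.0145467,0.137213,0.0089781,0.0342437
116.676,0.0119708,0.135383,0.00798681,0.0323313
118.19,0.011487,0.134987,0.0077915,0.0319854
130.52,0.00836237,0.131857,0.00644148,0.0298902
131.037,0.00825725,0.131729,0.0063929,0.0298249
147.166,0.00569571,0.127886,0.00512223,0.0283891
150,0.00535857,0.127239,0.00493983,0.0282287
165.281,0.0039288,0.12389,0.00411152,0.0276605
177.21,0.00314363,0.121431,0.00360774,0.0274544
185.625,0.00271002,0.119774,0.00330925,0.0273873
197.96,0.00220588,0.117454,0.00293873,0.0273657
208.473,0.00186932,0.115572,0.00267368,0.0273951
234.134,0.00128943,0.111314,0.00217117,0.0275633
261.08,0.000910004,0.107291,0.00179652,0.0277922
262.954,0.000889423,0.107027,0.00177474,0.0278083
295.32,0.000613508,0.102736,0.00146283,0.0280727
307.74,0.000537754,0.101217,0.00136909,0.0281634
331.671,0.000423187,0.0984635,0.00121822,0.0283171
372.496,0.000291907,0.0942274,0.00102727,0.0285148
400,0.000232415,0.0916526,0.000931945,0.0286051
418.346,0.000201352,0.0900433,0.000879297,0.028648
469.84,0.000138889,0.0859237,0.000765931,0.0287049
500,0.000113821,0.083746,0.000717043,0.0287014
527.672,9.58034e-05,0.0818788,0.000680504,0.0286784
592.622,6.60835e-05,0.0779164,0.000617505,0.0285642
662,4.63738e-05,0.07422,0.000573965,0.0283719
665.568,4.55832e-05,0.0740427,0.000572195,0.0283605
747.492,3.14425e-05,0.0702626,0.000540398,0.0280676
800,2.53041e-05,0.068097,0.000526592,0.0278554
839.5,2.16885e-05,0.0665802,0.000518491,0.0276868
942.833,1.49603e-05,0.0629988,0.000503506,0.0272213
1000,1.23923e-05,0.0612222,0.000497806,0.0269541
1058.89,1.03194e-05,0.0595214,0.000493197,0.0266751
1170,7.49907e-06,0.0566171,0.000486878,0.0261449
1189.22,7.11813e-06,0.0561505,0.000486017,0.0260533
1250,6.06892e-06,0.0547364,0.000483633,0.0257647
1330,4.97643e-06,0.0530049,0.000481129,0.0253884
1335.6,4.90996e-06,0.0528887,0.000480976,0.0253622
1500,3.3868e-06,0.0497385,0.000477456,0.0246088
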