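energy_keV,mu_pe,mu_incoh,mu_coh,mu_en
1,2866.66,0.00716847,2.52701,2720.15
1.12309,2037.82,0.00919995,2.4693,1939.38
1.26133,1448.62,0.0116351,2.40226,1382.72
1.41658,1029.78,0.0144814,2.32569,985.835
1.55804,778.433,0.0171114,2.25597,747.019
1.56116,773.869,0.0171694,2.25445,742.678
1.59095,732.038,0.0177228,2.23987,702.87
1.78678,520.382,0.0213215,2.14568,501.124
1.83706,479.611,0.0222292,2.12206,462.187
1.84074,5006.39,0.0222953,2.12035,4637.19
2.00671,3884.2,0.0252252,2.04453,3617.72
2.25372,2761.15,0.0293784,1.93831,2589.78
2.53112,1962.82,0.033736,1.82907,1853.07
2.84268,1395.3,0.0382773,1.71882,1325.39
3.19258,991.878,0.0430207,1.60926,947.638
3.1997,985.404,0.0431141,1.60717,941.554
3.2061,979.627,0.043198,1.6053,936.125
3.58555,705.095,0.0480309,1.50157,677.335
4,511.2,0.0530882,1.40234,493.481
4.02689,501.229,0.0534109,1.39633,483.996
4.52256,356.092,0.0592768,1.29341,345.501
5,264.74,0.0648138,1.20577,257.833
5.07923,252.708,0.065723,1.19211,246.252
5.70443,179.145,0.0727909,1.09149,175.245
6.40658,126.859,0.080445,0.990881,124.524
7.19516,89.7361,0.0885604,0.890331,88.3522
8,65.346,0.0961974,0.799325,64.4949
8.08081,63.4078,0.0969247,0.790785,62.5953
9.07546,44.7556,0.105265,0.693934,44.2829
10,33.4233,0.112012,0.616569,33.1243
10.1926,31.556,0.113301,0.601857,31.2829
11.4471,22.2252,0.120801,0.516557,22.0681
12.8562,15.6365,0.127628,0.439509,15.546
14.4386,10.9891,0.133733,0.371408,10.9366
15,9.78426,0.135581,0.350988,9.74017
16.2158,7.71467,0.139118,0.312173,7.68372
18.2118,5.41004,0.143792,0.261179,5.39156
20,4.05984,0.147048,0.225449,4.04765
20.4535,3.78977,0.14776,0.217555,3.77876
22,3.02906,0.149896,0.193531,3.02127
22.9711,2.65189,0.151034,0.180417,2.64566
24,2.31689,0.152094,0.167919,2.31206
25,2.04269,0.152999,0.156969,2.03903
25.7986,1.85365,0.153641,0.148972,1.85081
26,1.80964,0.153793,0.147051,1.80699
27,1.61033,0.15449,0.13804,1.6086
27.202,1.57362,0.15462,0.13632,1.57207
27.472,1.52626,0.154789,0.13407,1.52493
28,1.43892,0.155101,0.129828,1.43801
28.9741,1.29428,0.155623,0.122512,1.29412
29,1.29071,0.155636,0.122326,1.29056
30,1.16193,0.156101,0.115453,1.16248
30.98,1.05162,0.156497,0.109262,1.05282
31.71,0.978249,0.156756,0.104968,0.9799
32,0.950969,0.156852,0.103332,0.952795
32.5405,0.902734,0.157018,0.100382,0.904879
33,0.864228,0.157148,0.0979729,0.866636
34,0.787587,0.157399,0.0930186,0.790549
35,0.719629,0.157608,0.0884292,0.723118
35.492,0.68901,0.157696,0.0862944,0.69275
36,0.659165,0.157778,0.0841698,0.663159
36.5459,0.628957,0.157856,0.0819725,0.633217
38,0.556885,0.158015,0.07652,0.561828
40,0.47446,0.158133,0.0698613,0.480284
41.0443,0.437735,0.158152,0.0667219,0.443995
45,0.328178,0.15801,0.0565497,0.335964
46.0964,0.304321,0.157919,0.0541373,0.312498
49.772,0.239184,0.15748,0.0470745,0.248588
50.742,0.225105,0.157334,0.0454386,0.234813
51.7703,0.21134,0.157169,0.0437949,0.221362
55,0.174681,0.156579,0.0391694,0.185638
57.5,0.151841,0.156062,0.0360702,0.163474
58.1427,0.146609,0.155922,0.0353324,0.158409
59.3,0.137768,0.155662,0.0340593,0.149863
63.121,0.113104,0.154753,0.0303081,0.126121
65.2994,0.101595,0.154205,0.0284389,0.115104
70,0.0815193,0.152966,0.0249494,0.0960193
73.3371,0.070325,0.152052,0.0228467,0.085475
80,0.0533483,0.150177,0.0193709,0.0696814
82.364,0.0486271,0.149502,0.0183264,0.0653475
92.5021,0.0335875,0.146593,0.014684,0.0518062
93.614,0.0323303,0.146275,0.0143522,0.0506991
100,0.0261829,0.144459,0.0126486,0.045366
103.888,0.0231742,0.143366,0.0117568,0.0428167
109.78,0.01942,0.141733,0.0105766,0.0397118
116.676,0.0159744,0.139861,0.0094102,0.0369625
118.19,0.0153273,0.139456,0.00918033,0.0364601
130.52,0.0111504,0.136247,0.00759078,0.0333617
131.037,0.0110099,0.136116,0.00753357,0.0332629
147.166,0.00758832,0.132171,0.00603643,0.0310186
150,0.0071382,0.131506,0.00582145,0.0307531
165.281,0.00523007,0.128062,0.00484499,0.0297446
177.21,0.00418281,0.125532,0.00425106,0.0293014
185.625,0.00360469,0.123826,0.00389917,0.0291054
197.96,0.00293281,0.121436,0.00346246,0.0289364
208.473,0.00248445,0.119496,0.00315015,0.0288694
234.134,0.00171234,0.115105,0.00255834,0.0288762
261.08,0.00120756,0.110954,0.00211742,0.0290045
262.954,0.00118019,0.110681,0.00209179,0.0290153
295.32,0.000813417,0.106252,0.00172468,0.0292106
307.74,0.000712774,0.104683,0.00161426,0.0292831
331.671,0.000560628,0.101839,0.00143631,0.0294101
372.496,0.000386399,0.0974632,0.00121028,0.0295783
400,0.000307497,0.0948028,0.00109682,0.0296553
418.346,0.000266316,0.0931397,0.00103386,0.0296913
469.84,0.000183552,0.088882,0.000897213,0.0297334
500,0.000150358,0.0866309,0.000837611,0.0297231
527.672,0.000126508,0.0847007,0.000792671,0.0296946
592.622,8.71928e-05,0.0806041,0.000714079,0.0295687
662,6.11401e-05,0.076782,0.000658601,0.0293649
665.568,6.00955e-05,0.0765986,0.000656322,0.0293529
747.492,4.14193e-05,0.0726895,0.000614982,0.0290463
800,3.33175e-05,0.0704498,0.000596836,0.0288253
839.5,2.85473e-05,0.068881,0.000586158,0.02865
942.833,1.96755e-05,0.0651767,0.000566459,0.0281668
1000,1.62914e-05,0.063339,0.000559043,0.0278898
1058.89,1.35609e-05,0.0615796,0.000553109,0.0276006
1170,9.84779e-06,0.0585754,0.0005451,0.0270515
1189.22,9.34648e-06,0.0580926,0.000544022,0.0269567
1250,7.96605e-06,0.0566298,0.000541051,0.0266578
1330,6.52924e-06,0.0548386,0.000537953,0.0262683
1335.6,6.44183e-06,0.0547184,0.000537764,0.0262412
1500,4.43987e-06,0.0514595,0.000533421,0.0254614
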