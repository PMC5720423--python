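energy_keV,mu_pe,mu_incoh,mu_coh,mu_en
1,7905.8,0.00602226,1.2856,6475.61
1.12309,5350.98,0.00802485,1.25858,4433.99
1.26133,3621.77,0.0105969,1.22616,3036.04
1.41658,2451.37,0.0138454,1.1877,2078.84
1.55804,1780,0.0170837,1.1513,1523.89
1.56116,1768.07,0.0171577,1.15049,1513.98
1.59095,1659.19,0.0178694,1.1427,1423.43
1.78678,1123.01,0.0227453,1.09089,974.651
1.83706,1022.96,0.0240424,1.0775,890.275
1.84074,1016.1,0.0241379,1.07652,884.484
2.00671,760.1,0.0285104,1.03236,667.364
2.25372,514.468,0.0351467,0.967625,456.958
2.53112,348.214,0.0425706,0.897694,312.889
2.84268,235.686,0.0506297,0.824038,214.242
3.19258,159.522,0.0591107,0.748478,146.696
3.1997,158.332,0.0592759,0.747022,145.634
3.2061,157.271,0.0594243,0.745716,144.687
3.58555,107.971,0.0677609,0.673002,100.446
4,74.7446,0.0758345,0.603702,70.2979
4.02689,73.0797,0.076322,0.599548,68.7779
4.52256,49.5035,0.0845697,0.529796,47.1005
5,35.3911,0.0913232,0.47346,33.9593
5.07923,33.5819,0.0923448,0.465009,32.2635
5.70443,22.8141,0.0995661,0.405963,22.1059
6.40658,15.5215,0.106223,0.352958,15.1502
7.19516,10.5753,0.11236,0.305917,10.386
8,7.45811,0.117577,0.267877,7.35838
8.08081,7.21574,0.118054,0.264502,7.12201
9.07546,4.93061,0.123405,0.228223,4.88539
10,3.59066,0.127682,0.20143,3.56629
10.1926,3.37404,0.128507,0.196507,3.35243
11.4471,2.31222,0.133434,0.168754,2.30156
12.8562,1.58686,0.138221,0.144383,1.58106
14.4386,1.09063,0.142853,0.122889,1.08702
15,0.964495,0.144333,0.116385,0.96134
16.2158,0.750667,0.147269,0.103886,0.748268
18.2118,0.517424,0.151366,0.0871196,0.516023
20,0.383636,0.154353,0.0751194,0.383098
20.4535,0.357171,0.155018,0.0724426,0.356855
22,0.283221,0.157028,0.0642531,0.283671
22.9711,0.246908,0.158104,0.059763,0.247843
24,0.214871,0.159101,0.0554779,0.216319
25,0.18881,0.159943,0.0517244,0.190755
25.7986,0.170933,0.160533,0.0489862,0.17327
26,0.166782,0.160671,0.0483292,0.169217
27,0.148038,0.161294,0.0452514,0.150957
27.202,0.144596,0.161409,0.044665,0.147611
27.472,0.140159,0.161556,0.0438986,0.143302
28,0.131991,0.161824,0.0424553,0.135384
28.9741,0.118507,0.162259,0.0399724,0.122352
29,0.118175,0.16227,0.0399094,0.122031
30,0.106215,0.162639,0.0375859,0.110525
30.98,0.0960061,0.162934,0.0355011,0.10075
31.71,0.089234,0.163115,0.0340597,0.0942942
32,0.0867201,0.163178,0.0335115,0.0919041
32.5405,0.0822802,0.163284,0.0325249,0.0876926
33,0.0787406,0.163362,0.0317204,0.0843445
34,0.0717087,0.163496,0.0300705,0.0777211
35,0.0654881,0.163584,0.0285473,0.071898
35.492,0.06269,0.163613,0.0278404,0.0692914
36,0.0599654,0.163633,0.027138,0.0667618
36.5459,0.0572104,0.163644,0.0264126,0.0642134
38,0.050649,0.163625,0.0246173,0.058187
40,0.0431647,0.163498,0.0224335,0.0514045
41.0443,0.0398369,0.163393,0.0214071,0.0484281
45,0.0299322,0.162796,0.0180938,0.0397704
46.0964,0.0277795,0.162586,0.0173107,0.0379414
49.772,0.0219079,0.161774,0.0150228,0.0330936
50.742,0.0206396,0.161536,0.014494,0.0320807
51.7703,0.0193997,0.161276,0.0139629,0.0311056
55,0.0160974,0.160408,0.0124704,0.028596
57.5,0.0140391,0.159694,0.0114719,0.0271143
58.1427,0.0135673,0.159506,0.0112343,0.026786
59.3,0.01277,0.159163,0.0108246,0.0262421
63.121,0.0105431,0.157997,0.00961857,0.0248117
65.2994,0.00950222,0.157316,0.0090183,0.0241992
70,0.0076826,0.155819,0.00789893,0.0232473
73.3371,0.00666477,0.154743,0.00722531,0.022803
80,0.0051145,0.152587,0.00611354,0.0223062
82.364,0.0046814,0.151824,0.00577994,0.0222205
92.5021,0.00329303,0.148594,0.00461882,0.0221883
93.614,0.00317619,0.148245,0.00451326,0.0222083
100,0.00260239,0.146269,0.00397192,0.0223803
103.888,0.00231978,0.145089,0.00368906,0.0225207
109.78,0.00196501,0.143337,0.00331535,0.0227669
116.676,0.00163623,0.141343,0.00294688,0.0230861
118.19,0.00157403,0.140914,0.00287438,0.0231589
130.52,0.0011681,0.13753,0.00237429,0.0237644
131.037,0.00115431,0.137392,0.00235633,0.0237898
147.166,0.000814323,0.133271,0.00188808,0.0245635
150,0.000768956,0.13258,0.00182113,0.0246936
165.281,0.000574476,0.129012,0.00151831,0.0253572
177.21,0.000465914,0.126403,0.00133542,0.0258275
185.625,0.000405273,0.124648,0.00122769,0.0261342
197.96,0.000334017,0.122196,0.00109485,0.0265474
208.473,0.000285906,0.120211,0.00100058,0.0268675
234.134,0.000201697,0.115728,0.000824208,0.0275375
261.08,0.000145381,0.111506,0.000695551,0.0280958
262.954,0.00014229,0.111228,0.00068817,0.0281298
295.32,0.000100381,0.106734,0.000583937,0.0286346
307.74,8.86907e-05,0.105144,0.000553237,0.0287914
331.671,7.08151e-05,0.102266,0.00050454,0.0290451
372.496,4.99576e-05,0.0978437,0.000444313,0.0293568
400,4.03286e-05,0.0951582,0.000414848,0.029498
418.346,3.52433e-05,0.0934806,0.000398726,0.0295672
469.84,2.4863e-05,0.0891894,0.000364233,0.0296753
500,2.06225e-05,0.0869224,0.000349336,0.0296909
527.672,1.75399e-05,0.0849795,0.000338112,0.0296808
592.622,1.23738e-05,0.0808585,0.000318304,0.0295847
662,8.87146e-06,0.0770163,0.000303874,0.0293998
665.568,8.7293e-06,0.0768321,0.000303265,0.0293886
747.492,6.15822e-06,0.0729048,0.000291836,0.0290948
800,5.02157e-06,0.0706554,0.000286471,0.0288791
839.5,4.34441e-06,0.0690803,0.000283156,0.0287067
942.833,3.06483e-06,0.0653616,0.000276602,0.0282283
1000,2.56784e-06,0.0635172,0.000273945,0.0279528
1058.89,2.16213e-06,0.0617515,0.000271734,0.0276647
1170,1.60187e-06,0.0587369,0.000268649,0.0271165
1189.22,1.52531e-06,0.0582526,0.000268229,0.0270217
1250,1.31309e-06,0.0567849,0.000267078,0.0267229
1330,1.08973e-06,0.0549878,0.0002659,0.0263331
1335.6,1.07605e-06,0.0548672,0.00026583,0.026306
1500,7.59117e-07,0.0515978,0.000264303,0.0255252
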