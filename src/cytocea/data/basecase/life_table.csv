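age,qx
50,0.0021999280994770025
51,0.002419170415230624
52,0.002660262169167447
53,0.0029253808512819577
54,0.003216920957728542
55,0.0035375156174069352
56,0.003890060373828419
57,0.00427773933705558
58,0.004704053941914433
59,0.005172854572217058
60,0.005688375336618037
61,0.00625527231019295
62,0.006878665587128793
63,0.0075641855243373714
64,0.008318023593654276
65,0.009146988301909771
66,0.010058566683929956
67,0.011060991923859977
68,0.012163317715550934
69,0.013375500033617786
70,0.014708487053707284
71,0.016174318034116862
72,0.017786232051842425
73,0.01955878757513624
74,0.021507993952528965
75,0.02365145600589715
76,0.02600853303351025
77,0.028600513659139307
78,0.03145080810642761
79,0.03458515963510493
80,0.03803187704869299
81,0.04182209037366246
82,0.04599003201928207
83,0.050573345957536535
84,0.05561342771556095
85,0.061155798251332036
86,0.06725051508938272
87,0.0739526244298313
88,0.08132265831407896
89,0.08942718133747132
90,0.09833939184671814
91,0.10813978305195926
92,0.11891687002450269
93,0.13076798914632426
94,0.14380017723178953
95,0.1581311382616404
96,0.17389030646058296
97,0.19122001531997188
98,0.2102767831239561
99,0.2312327265896894
100,0.254277115389305
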