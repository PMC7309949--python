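age,qx_male,qx_female
0,0.002000,0.001800
1,0.000224,0.000212
2,0.000227,0.000213
3,0.000229,0.000214
4,0.000232,0.000215
5,0.000235,0.000217
6,0.000239,0.000218
7,0.000242,0.000220
8,0.000247,0.000222
9,0.000251,0.000224
10,0.000256,0.000227
11,0.000262,0.000230
12,0.000268,0.000232
13,0.000275,0.000236
14,0.000282,0.000239
15,0.000290,0.000243
16,0.000299,0.000247
17,0.000309,0.000252
18,0.000319,0.000257
19,0.000331,0.000263
20,0.000344,0.000269
21,0.000358,0.000276
22,0.000374,0.000283
23,0.000391,0.000291
24,0.000410,0.000300
25,0.000431,0.000310
26,0.000453,0.000321
27,0.000478,0.000333
28,0.000506,0.000346
29,0.000536,0.000360
30,0.000569,0.000376
31,0.000605,0.000394
32,0.000645,0.000413
33,0.000689,0.000434
34,0.000738,0.000457
35,0.000791,0.000482
36,0.000849,0.000510
37,0.000913,0.000540
38,0.000983,0.000574
39,0.001060,0.000610
40,0.001145,0.000651
41,0.001238,0.000695
42,0.001340,0.000744
43,0.001453,0.000798
44,0.001576,0.000857
45,0.001712,0.000922
46,0.001861,0.000993
47,0.002024,0.001071
48,0.002204,0.001157
49,0.002402,0.001251
50,0.002619,0.001354
51,0.002857,0.001468
52,0.003119,0.001593
53,0.003407,0.001731
54,0.003723,0.001881
55,0.004070,0.002047
56,0.004452,0.002229
57,0.004871,0.002429
58,0.005331,0.002649
59,0.005837,0.002890
60,0.006392,0.003155
61,0.007002,0.003447
62,0.007673,0.003767
63,0.008409,0.004118
64,0.009219,0.004504
65,0.010107,0.004929
66,0.011084,0.005395
67,0.012157,0.005907
68,0.013335,0.006469
69,0.014630,0.007087
70,0.016052,0.007766
71,0.017614,0.008511
72,0.019331,0.009330
73,0.021216,0.010230
74,0.023287,0.011219
75,0.025563,0.012305
76,0.028063,0.013498
77,0.030809,0.014809
78,0.033826,0.016249
79,0.037140,0.017830
80,0.040780,0.019568
81,0.044780,0.021477
82,0.049174,0.023574
83,0.054001,0.025878
84,0.059303,0.028408
85,0.065129,0.031189
86,0.071528,0.034243
87,0.078558,0.037598
88,0.086281,0.041284
89,0.094765,0.045333
90,0.104085,0.049782
91,0.114324,0.054668
92,0.125572,0.060037
93,0.137929,0.065934
94,0.151503,0.072413
95,0.166416,0.079530
96,0.182798,0.087349
97,0.200795,0.095938
98,0.220565,0.105374
99,0.242285,0.115740
100,0.266144,0.127128
101,0.292356,0.139638
102,0.321151,0.153381
103,0.352783,0.168478
104,0.387534,0.185064
105,0.425709,0.203284
106,0.467648,0.223300
107,0.513719,0.245289
108,0.564331,0.269445
109,0.619932,0.295981
110,0.681013,0.325133
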