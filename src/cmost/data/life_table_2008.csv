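age,qx
0,0.006800
1,0.000450
2,0.000450
3,0.000450
4,0.000450
5,0.000140
6,0.000140
7,0.000140
8,0.000140
9,0.000140
10,0.000180
11,0.000180
12,0.000180
13,0.000180
14,0.000180
15,0.000620
16,0.000620
17,0.000620
18,0.000620
19,0.000620
20,0.000950
21,0.000950
22,0.000950
23,0.000950
24,0.000950
25,0.000980
26,0.000980
27,0.000980
28,0.000980
29,0.000980
30,0.000680
31,0.000743
32,0.000811
33,0.000885
34,0.000967
35,0.001056
36,0.001153
37,0.001259
38,0.001375
39,0.001501
40,0.001639
41,0.001790
42,0.001955
43,0.002135
44,0.002331
45,0.002546
46,0.002780
47,0.003035
48,0.003315
49,0.003620
50,0.003952
51,0.004316
52,0.004713
53,0.005147
54,0.005620
55,0.006137
56,0.006702
57,0.007318
58,0.007991
59,0.008726
60,0.009529
61,0.010406
62,0.011363
63,0.012408
64,0.013549
65,0.014796
66,0.016157
67,0.017643
68,0.019266
69,0.021038
70,0.022973
71,0.025087
72,0.027394
73,0.029914
74,0.032666
75,0.035671
76,0.038952
77,0.042535
78,0.046448
79,0.051436
80,0.056959
81,0.063076
82,0.069849
83,0.077350
84,0.085656
85,0.094854
86,0.105040
87,0.116319
88,0.128810
89,0.142642
90,0.157959
91,0.174922
92,0.193705
93,0.214506
94,0.237540
95,0.263048
96,0.291295
97,0.322576
98,0.357215
99,0.395574
100,0.438052
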