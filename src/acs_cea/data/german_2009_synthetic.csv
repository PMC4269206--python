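# Synthetic stand-in for the German period life table circa 2009 (Sterbetafel
# 2009/2011). Not transcribed from official statistics: built by log-linear
# interpolation over age anchors with sex-specific levels calibrated to
# published remaining life expectancies (e60 21.3/25.0, e65 17.5/20.7 years).
age,sex,qx
0,male,0.003796
1,male,0.000285
2,male,0.000216
3,male,0.000164
4,male,0.000125
5,male,9.5e-05
6,male,9.5e-05
7,male,9.5e-05
8,male,9.5e-05
9,male,9.5e-05
10,male,9.5e-05
11,male,0.000118
12,male,0.000147
13,male,0.000183
14,male,0.000229
15,male,0.000285
16,male,0.000327
17,male,0.000376
18,male,0.000432
19,male,0.000496
20,male,0.000569
21,male,0.000569
22,male,0.000569
23,male,0.000569
24,male,0.000569
25,male,0.000569
26,male,0.000587
27,male,0.000606
28,male,0.000625
29,male,0.000644
30,male,0.000664
31,male,0.000699
32,male,0.000735
33,male,0.000772
34,male,0.000812
35,male,0.000854
36,male,0.000933
37,male,0.001019
38,male,0.001113
39,male,0.001216
40,male,0.001329
41,male,0.00148
42,male,0.001648
43,male,0.001836
44,male,0.002045
45,male,0.002278
46,male,0.002523
47,male,0.002794
48,male,0.003094
49,male,0.003427
50,male,0.003796
51,male,0.004196
52,male,0.004638
53,male,0.005126
54,male,0.005666
55,male,0.006263
56,male,0.006873
57,male,0.007542
58,male,0.008276
59,male,0.009081
60,male,0.009964
61,male,0.01084
62,male,0.011793
63,male,0.01283
64,male,0.013957
65,male,0.015184
66,male,0.016535
67,male,0.018005
68,male,0.019607
69,male,0.021351
70,male,0.02325
71,male,0.025516
72,male,0.028002
73,male,0.030731
74,male,0.033725
75,male,0.037011
76,male,0.041117
77,male,0.045679
78,male,0.050748
79,male,0.056378
80,male,0.062634
81,male,0.069991
82,male,0.078211
83,male,0.087398
84,male,0.097663
85,male,0.109135
86,male,0.121416
87,male,0.135078
88,male,0.150279
89,male,0.16719
90,male,0.186003
91,male,0.203865
92,male,0.223441
93,male,0.244898
94,male,0.268414
95,male,0.294189
96,male,0.314086
97,male,0.335328
98,male,0.358006
99,male,0.382219
100,male,0.408069
101,male,0.428659
102,male,0.450289
103,male,0.47301
104,male,0.496877
105,male,0.521949
106,male,0.544209
107,male,0.567418
108,male,0.591617
109,male,0.616848
110,male,1.0
0,female,0.003199
1,female,0.000194
2,female,0.000163
3,female,0.000137
4,female,0.000115
5,female,9.7e-05
6,female,9.7e-05
7,female,9.7e-05
8,female,9.7e-05
9,female,9.7e-05
10,female,9.7e-05
11,female,0.000111
12,female,0.000128
13,female,0.000147
14,female,0.000169
15,female,0.000194
16,female,0.000194
17,female,0.000194
18,female,0.000194
19,female,0.000194
20,female,0.000194
21,female,0.00021
22,female,0.000228
23,female,0.000247
24,female,0.000268
25,female,0.000291
26,female,0.000291
27,female,0.000291
28,female,0.000291
29,female,0.000291
30,female,0.000291
31,female,0.000322
32,female,0.000357
33,female,0.000395
34,female,0.000438
35,female,0.000485
36,female,0.000533
37,female,0.000585
38,female,0.000643
39,female,0.000706
40,female,0.000776
41,female,0.000867
42,female,0.00097
43,female,0.001085
44,female,0.001214
45,female,0.001357
46,female,0.001499
47,female,0.001655
48,female,0.001828
49,female,0.002019
50,female,0.00223
51,female,0.002452
52,female,0.002697
53,female,0.002966
54,female,0.003262
55,female,0.003587
56,female,0.003883
57,female,0.004204
58,female,0.00455
59,female,0.004926
60,female,0.005332
61,female,0.005776
62,female,0.006256
63,female,0.006776
64,female,0.00734
65,female,0.00795
66,female,0.008677
67,female,0.00947
68,female,0.010336
69,female,0.011281
70,female,0.012313
71,female,0.013768
72,female,0.015395
73,female,0.017214
74,female,0.019248
75,female,0.021523
76,female,0.024356
77,female,0.027562
78,female,0.031191
79,female,0.035297
80,female,0.039943
81,female,0.045726
82,female,0.052346
83,female,0.059923
84,female,0.068599
85,female,0.078529
86,female,0.089757
87,female,0.102589
88,female,0.117256
89,female,0.13402
90,female,0.153181
91,female,0.171753
92,female,0.192577
93,female,0.215926
94,female,0.242106
95,female,0.27146
96,female,0.291532
97,female,0.313088
98,female,0.336238
99,female,0.361099
100,female,0.387799
101,female,0.408692
102,female,0.43071
103,female,0.453914
104,female,0.478368
105,female,0.504139
106,female,0.526802
107,female,0.550484
108,female,0.57523
109,female,0.601089
110,female,1.0
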