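k,q_0.05,q_0.1
2,1.960,1.645
3,2.343,2.052
4,2.569,2.291
5,2.728,2.459
6,2.850,2.589
7,2.949,2.693
8,3.031,2.780
9,3.102,2.855
10,3.164,2.920
11,3.219,2.978
12,3.268,3.030
13,3.313,3.077
14,3.354,3.120
15,3.391,3.159
16,3.426,3.196
17,3.458,3.230
18,3.489,3.261
19,3.517,3.291
20,3.544,3.319
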