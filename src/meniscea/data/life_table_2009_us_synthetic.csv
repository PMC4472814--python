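age,annual_death_prob
40,0.001393
41,0.001532
42,0.001684
43,0.001852
44,0.002037
45,0.002240
46,0.002463
47,0.002708
48,0.002978
49,0.003275
50,0.003602
51,0.003961
52,0.004355
53,0.004789
54,0.005267
55,0.005791
56,0.006369
57,0.007003
58,0.007701
59,0.008469
60,0.009313
61,0.010241
62,0.011261
63,0.012384
64,0.013618
65,0.014975
66,0.016467
67,0.018108
68,0.019913
69,0.021898
70,0.024080
71,0.026480
72,0.029119
73,0.032021
74,0.035212
75,0.038721
76,0.042580
77,0.046823
78,0.051490
79,0.056621
80,0.062264
81,0.068469
82,0.075292
83,0.082796
84,0.091047
85,0.100121
86,0.110099
87,0.121071
88,0.133137
89,0.146405
90,0.160996
91,0.177041
92,0.194684
93,0.214086
94,0.235422
95,0.258884
96,0.284684
97,0.313055
98,0.344254
99,0.378562
100,0.416289
101,0.457776
102,0.503397
103,0.553565
104,0.608733
105,0.669399
106,0.736110
107,0.809470
108,0.890141
109,0.978851
110,1.000000
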