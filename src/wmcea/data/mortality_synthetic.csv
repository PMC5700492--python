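age,annual_q
40,0.001298
41,0.001401
42,0.001514
43,0.001638
44,0.001774
45,0.001922
46,0.002084
47,0.002262
48,0.002456
49,0.002668
50,0.002901
51,0.003155
52,0.003433
53,0.003738
54,0.004071
55,0.004435
56,0.004834
57,0.005271
58,0.005748
59,0.006271
60,0.006842
61,0.007468
62,0.008152
63,0.008901
64,0.009720
65,0.010617
66,0.011598
67,0.012671
68,0.013846
69,0.015131
70,0.016537
71,0.018076
72,0.019759
73,0.021601
74,0.023617
75,0.025822
76,0.028235
77,0.030875
78,0.033764
79,0.036924
80,0.040383
81,0.044167
82,0.048308
83,0.052838
84,0.057795
85,0.063219
86,0.069154
87,0.075648
88,0.082753
89,0.090528
90,0.099034
91,0.108342
92,0.118526
93,0.129669
94,0.141862
95,0.155203
96,0.169800
97,0.185772
98,0.203248
99,0.222370
100,0.243293
101,0.266186
102,0.291235
103,0.318643
104,0.348632
105,0.381445
106,0.417348
107,0.456633
108,0.499617
109,0.546650
110,0.598111
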