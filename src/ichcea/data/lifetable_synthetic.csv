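age,qx
18,0.0006001622691454989
19,0.0006109308637285427
20,0.0006228556919924966
21,0.0006360608836871728
22,0.0006506838911137791
23,0.0006668769181780165
24,0.0006848085025450423
25,0.0007046652672568765
26,0.0007266538599108863
27,0.000751003099419556
28,0.000777966352495274
29,0.0008078241643454387
30,0.0008408871706557797
31,0.0008774993207933957
32,0.0009180414453145991
33,0.00096293520434243
34,0.0010126474572075272
35,0.0010676950979753297
36,0.001128650406131082
37,0.0011961469668175795
38,0.0012708862206498583
39,0.0013536447093233095
40,0.0014452820900250352
41,0.0015467499991169698
42,0.001659101853726419
43,0.0017835036888201872
44,0.0019212461371125311
45,0.002073757669811882
46,0.0022426192278298673
47,0.0024295803856881903
48,0.00263657720404864
49,0.0028657519415823396
50,0.003119474812847023
51,0.003400367995967324
52,0.0037113321122306253
53,0.004055575419198099
54,0.004436645979541631
55,0.004858467089450702
56,0.005325376272970472
57,0.00584216817179839
58,0.0064141416835765686
59,0.00704715172513426
60,0.007747666019889077
61,0.008522827329943139
62,0.009380521572341816
63,0.010329452274230877
64,0.011379221831669506
65,0.012540420039613531
66,0.013824720353582398
67,0.015244984323638744
68,0.01681537460470328
69,0.01855147688920422
70,0.020470431022853952
71,0.022591071445025257
72,0.024934076933364913
73,0.027522129417922536
74,0.030380081351263133
75,0.033535130763733156
76,0.03701700268084551
77,0.04085813501364455
78,0.045093866331203714
79,0.04976262206262139
80,0.05490609462695362
81,0.060569411724161415
82,0.06680128550766695
83,0.07365413356873785
84,0.08118416056588162
85,0.08945138690507692
86,0.0985196081048656
87,0.10845626536561548
88,0.11933220443013759
89,0.1312212961336967
90,0.14419988820461682
91,0.15834605406798685
92,0.17373860088807624
93,0.19045579623635178
94,0.20857377110820496
95,0.2281645572184544
96,0.24929371946424184
97,0.27201755124828353
98,0.2963798123143532
99,0.32240800735645736
100,0.3501092305336404
101,0.37946563773827546
102,0.41042965635404505
103,0.4429191020204881
104,0.4768124432170284
105,0.5119445351794257
106,0.5481032301540393
107,0.5850273533431597
108,0.6224066010938911
109,0.6598839534457351
110,1.0
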