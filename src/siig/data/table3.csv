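genotype,YLD_Ahvaz,SIIG_Ahvaz,rank_Ahvaz,YLD_Gonbad,SIIG_Gonbad,rank_Gonbad,YLD_Zabol,SIIG_Zabol,rank_Zabol,YLD_Darab,SIIG_Darab,rank_Darab
1,850,0.303,103,3183,0.503,59,7138,0.758,3,7780,0.612,3
2,1200,0.341,93,3475,0.540,49,5583,0.535,53,5313,0.490,32
3,1050,0.372,78,4400,0.731,5,6708,0.682,14,6020,0.528,14
4,1100,0.366,81,3722,0.696,8,5583,0.709,7,5220,0.460,50
5,1500,0.463,43,3538,0.566,41,6694,0.735,4,5497,0.498,29
6,1150,0.363,83,2772,0.536,51,5416,0.614,29,3787,0.395,86
7,1300,0.363,82,3605,0.639,16,5291,0.549,49,3780,0.351,102
8,1150,0.440,50,2982,0.472,72,4944,0.498,70,4370,0.434,64
9,1400,0.447,47,2903,0.457,77,3930,0.394,97,6200,0.530,12
10,800,0.266,108,2860,0.465,74,3416,0.372,103,3053,0.337,106
11,1100,0.396,64,3408,0.571,37,5805,0.646,19,3710,0.402,81
12,1100,0.328,98,2977,0.497,63,4416,0.474,74,4283,0.454,52
13,1800,0.543,19,2752,0.420,83,4000,0.375,102,4947,0.450,54
14,1550,0.460,44,2667,0.463,75,4569,0.458,80,5170,0.450,55
15,1900,0.577,11,3135,0.500,62,6513,0.683,13,4930,0.465,46
16,1600,0.486,36,3057,0.481,68,6527,0.703,10,5390,0.505,25
17,1700,0.503,29,2787,0.544,47,5180,0.534,55,3320,0.331,108
18,1650,0.539,20,3048,0.505,56,7263,0.722,5,4367,0.433,65
19,1300,0.391,67,3418,0.489,67,5652,0.578,39,6317,0.563,7
20,1600,0.473,40,2478,0.370,98,4305,0.413,92,6300,0.510,21
21,1300,0.387,69,2782,0.467,73,3458,0.406,93,5920,0.509,23
22,700,0.249,111,3160,0.512,55,3555,0.362,104,5820,0.489,34
23,1000,0.311,101,3058,0.553,45,6138,0.679,15,5457,0.491,31
24,1100,0.337,94,3363,0.578,33,4500,0.495,71,4360,0.416,71
25,800,0.250,110,3403,0.576,35,5027,0.558,45,3683,0.578,6
26,600,0.267,107,3647,0.652,13,6347,0.707,8,4240,0.412,73
27,950,0.367,80,3638,0.618,22,4569,0.488,72,5840,0.501,28
28,1500,0.413,61,2710,0.419,84,4291,0.435,86,4420,0.394,87
29,1200,0.336,95,3667,0.577,34,6305,0.628,24,4600,0.425,67
30,1200,0.355,87,2932,0.472,71,4486,0.467,78,4000,0.399,85
31,1400,0.360,86,2882,0.428,79,5222,0.529,58,3833,0.362,95
32,1100,0.296,104,2665,0.552,46,3555,0.422,88,3617,0.353,101
33,1700,0.517,25,3255,0.493,65,3944,0.468,77,4747,0.423,68
34,1400,0.433,52,3712,0.529,52,2680,0.330,106,3737,0.384,90
35,1450,0.442,49,3905,0.591,30,2805,0.337,105,4270,0.407,76
36,1500,0.474,39,4687,0.740,4,4333,0.520,62,3170,0.357,98
37,2700,0.719,1,2997,0.425,81,3611,0.422,89,4140,0.405,79
38,2000,0.648,3,3482,0.676,9,4472,0.574,40,3063,0.342,105
39,1800,0.555,18,3067,0.568,40,4208,0.523,61,3107,0.306,110
40,1800,0.583,10,3367,0.635,20,4750,0.608,30,3540,0.355,99
41,1800,0.560,15,3720,0.617,23,4916,0.594,32,4010,0.385,89
42,1700,0.537,21,3140,0.504,57,3805,0.446,81,3227,0.347,104
43,1250,0.423,55,3502,0.543,48,4472,0.532,57,3080,0.326,109
44,1000,0.386,70,3183,0.560,43,5152,0.563,43,4667,0.480,39
45,1750,0.557,17,3302,0.492,66,4222,0.516,67,4403,0.460,51
46,1400,0.431,53,2688,0.351,99,5277,0.616,27,4420,0.406,78
47,1200,0.395,65,2622,0.389,90,4388,0.502,69,3150,0.333,107
48,1300,0.416,59,3585,0.538,50,4875,0.580,38,3993,0.400,83
49,1300,0.446,48,1888,0.232,111,4027,0.460,79,3567,0.351,103
50,1700,0.483,37,2158,0.306,106,3166,0.380,100,4330,0.410,75
51,1600,0.483,38,2713,0.503,58,4819,0.592,33,5320,0.486,36
52,1400,0.416,58,2688,0.378,94,5472,0.667,18,3983,0.359,97
53,1400,0.418,56,2663,0.399,89,5000,0.581,37,3947,0.378,91
54,1600,0.514,26,2267,0.315,103,7319,0.773,1,4137,0.413,72
55,1800,0.501,31,2307,0.382,92,5638,0.616,28,5610,0.540,11
56,1800,0.534,22,2202,0.307,105,6333,0.761,2,5997,0.527,15
57,1550,0.492,32,1660,0.298,108,5666,0.633,23,4860,0.436,60
58,1250,0.374,77,2120,0.333,101,5236,0.564,42,6410,0.560,8
59,1100,0.376,75,2142,0.370,97,5069,0.618,25,4317,0.399,84
60,1100,0.346,90,1163,0.263,109,3888,0.377,101,3337,0.353,100
61,1500,0.451,45,2083,0.332,102,4541,0.518,64,3933,0.412,74
62,1400,0.393,66,2660,0.426,80,5805,0.674,17,5430,0.510,22
63,2100,0.601,8,2090,0.315,104,3138,0.326,107,6087,0.518,18
64,1800,0.567,12,3283,0.648,15,3319,0.417,91,5323,0.490,33
65,1300,0.412,62,3142,0.528,53,5333,0.585,35,3757,0.377,93
66,1700,0.532,23,3480,0.586,31,3736,0.420,90,3970,0.393,88
67,1800,0.566,13,3452,0.570,39,4263,0.471,75,4653,0.454,53
68,1650,0.491,33,2953,0.455,78,4527,0.516,66,4600,0.418,70
69,1800,0.509,28,2937,0.408,88,3750,0.399,94,5110,0.466,45
70,1700,0.490,34,2745,0.415,85,5583,0.635,21,4260,0.443,57
71,2200,0.638,4,2048,0.256,110,4805,0.566,41,3383,0.377,92
72,1900,0.591,9,2312,0.385,91,4263,0.446,82,6017,0.595,5
73,1200,0.361,84,2690,0.495,64,4902,0.562,44,5223,0.552,9
74,950,0.308,102,3397,0.638,18,5180,0.589,34,4000,0.485,38
75,1450,0.439,51,4147,0.619,21,4680,0.545,51,4017,0.403,80
76,1000,0.336,97,3783,0.649,14,4763,0.532,56,4630,0.443,58
77,850,0.275,106,3513,0.637,19,5250,0.557,46,4550,0.407,77
78,850,0.281,105,3347,0.614,25,4486,0.476,73,5797,0.505,26
79,1200,0.377,74,3347,0.607,28,3583,0.395,96,4807,0.471,42
80,1000,0.353,89,4172,0.752,2,4638,0.513,68,5370,0.501,27
81,1400,0.414,60,3302,0.615,24,1944,0.258,111,5190,0.466,44
82,1200,0.368,79,2827,0.565,42,6152,0.699,11,4943,0.479,40
83,750,0.257,109,3143,0.638,17,4111,0.441,83,4950,0.462,49
84,1000,0.342,92,3740,0.744,3,3097,0.399,95,4847,0.435,61
85,900,0.411,63,3553,0.654,12,3888,0.440,84,5440,0.527,16
86,1300,0.449,46,3955,0.656,11,4250,0.470,76,8360,0.659,1
87,1500,0.489,35,3702,0.608,27,4902,0.537,52,7020,0.621,2
88,1350,0.378,73,2207,0.348,100,4944,0.555,47,5600,0.487,35
89,1200,0.376,76,2683,0.408,87,5833,0.697,12,4927,0.467,43
90,1300,0.430,54,2762,0.459,76,5986,0.644,20,4707,0.462,48
91,1300,0.418,57,2892,0.480,70,4152,0.438,85,450,0.198,111
92,1200,0.360,85,2583,0.423,82,4347,0.424,87,4660,0.435,63
93,1000,0.355,88,2147,0.302,107,3125,0.297,110,5700,0.495,30
94,800,0.312,100,2513,0.381,93,3180,0.304,109,6187,0.518,19
95,950,0.343,91,2257,0.372,96,5208,0.535,54,6017,0.509,24
96,1050,0.326,99,2442,0.374,95,6444,0.712,6,5260,0.463,47
97,1000,0.336,96,3682,0.609,26,6208,0.678,16,5000,0.474,41
98,1200,0.381,71,2650,0.415,86,5833,0.603,31,4803,0.439,59
99,1900,0.601,7,3548,0.713,6,4180,0.519,63,5883,0.513,20
100,1750,0.501,30,2833,0.501,61,4916,0.516,65,5160,0.430,66
101,1350,0.388,68,2807,0.501,60,5166,0.550,48,4877,0.448,56
102,1850,0.509,27,3192,0.599,29,5000,0.527,59,4267,0.372,94
103,2000,0.518,24,3752,0.662,10,5083,0.526,60,3820,0.359,96
104,2100,0.613,6,2735,0.481,69,6222,0.617,26,4933,0.435,62
105,2400,0.637,5,4242,0.761,1,5305,0.547,50,6443,0.526,17
106,2100,0.560,16,3108,0.582,32,3805,0.391,98,4220,0.401,82
107,2000,0.653,2,4103,0.706,7,3250,0.383,99,3800,0.422,69
108,1950,0.562,14,3206,0.559,44,6425,0.706,9,6957,0.611,4
109,1500,0.470,42,3450,0.570,38,4967,0.581,36,6107,0.529,13
110,1200,0.380,72,3153,0.576,36,5814,0.635,22,4671,0.485,37
111,1617,0.471,41,3217,0.519,54,3194,0.310,108,7107,0.544,10
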