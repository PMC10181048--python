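genotype,DHE,DHE_rank,DMA,DMA_rank,GFP,GFP_rank,PLH,PLH_rank,TKW,TKW_rank,YLD,YLD_rank,SIIG,SIIG_rank
1,106,108,139,108,33,95,85.8,44,37.0,45,4738,1,0.687,4
2,105,104,137,82,32,105,84.5,30,32.3,108,3893,19,0.517,52
3,103,75,137,83,34,75,85.8,44,38.5,44,4545,4,0.700,3
4,100,31,135,44,36,25,96.8,103,46.3,2,3906,18,0.634,9
5,104,97,137,84,34,75,82.0,19,34.4,92,4307,6,0.632,11
6,102,58,135,44,33,95,81.8,15,41.0,21,3281,81,0.516,53
7,102,58,132,5,30,111,91.5,84,39.0,36,3494,55,0.469,76
8,102,58,134,21,32,105,81.8,15,38.6,40,3361,74,0.504,59
9,103,75,134,22,31,110,86.5,52,38.6,41,3608,42,0.522,49
10,104,97,137,84,33,95,85.3,37,38.3,47,2532,109,0.335,109
11,105,104,139,109,34,75,79.3,6,38.7,38,3506,52,0.557,33
12,103,75,138,99,35,52,82.3,20,37.0,66,3194,91,0.469,75
13,103,75,133,15,31,110,86.0,47,35.0,83,3375,70,0.439,90
14,103,75,134,22,32,105,88.3,73,38.4,45,3489,56,0.489,64
15,101,45,135,44,34,75,82.3,20,34.7,87,4120,10,0.623,14
16,102,58,135,44,33,95,82.5,22,35.3,82,4143,9,0.613,17
17,101,45,131,2,31,110,85.5,40,37.9,50,3247,84,0.446,87
18,101,45,135,45,34,75,81.0,12,36.1,75,4082,12,0.634,10
19,104,97,136,61,33,95,84.3,29,34.1,96,4172,8,0.598,21
20,104,97,137,84,32,105,85.5,40,31.8,109,3671,33,0.474,74
21,100,31,134,22,35,52,86.8,58,37.6,54,3365,71,0.496,63
22,103,75,135,46,33,95,89.0,76,36.6,71,3309,78,0.442,89
23,103,75,137,85,35,52,95.5,99,42.7,10,3913,17,0.608,18
24,105,104,139,110,34,75,94.0,96,41.8,18,3331,77,0.481,71
25,101,45,137,85,36,25,71.8,1,38.3,46,3228,88,0.540,42
26,104,97,137,86,34,75,87.3,64,39.2,31,3708,31,0.565,31
27,103,75,138,100,35,52,86.5,52,40.0,25,3749,29,0.594,22
28,101,45,134,22,33,95,97.8,105,37.0,68,3230,87,0.382,103
29,103,75,138,101,35,52,95.8,100,34.3,95,3943,16,0.521,50
30,100,31,136,61,36,25,91.8,86,34.7,86,3154,95,0.402,99
31,102,58,136,61,34,75,96.5,102,32.7,107,3334,76,0.377,105
32,97,5,132,6,35,52,101.0,109,43.9,5,2734,107,0.390,101
33,98,11,135,46,37,11,92.3,88,34.9,84,3411,65,0.467,78
34,99,22,134,22,36,25,87.0,61,33.9,99,2882,104,0.371,106
35,98,11,133,15,36,25,89.5,80,34.4,91,3108,97,0.399,100
36,96,2,134,22,38,4,87.5,67,38.5,42,3422,63,0.541,41
37,98,11,132,7,34,75,85.5,40,33.1,104,3362,73,0.445,88
38,96,2,132,8,35,52,89.8,81,46.4,1,3254,82,0.543,40
39,97,5,131,2,34,75,100.3,107,45.5,3,3045,99,0.458,81
40,95,1,132,9,37,11,91.5,84,43.9,6,3364,72,0.554,35
41,99,22,134,23,36,25,92.8,92,39.9,27,3612,41,0.549,37
42,96,2,132,10,36,25,83.0,24,34.3,94,2968,102,0.414,96
43,97,5,133,15,36,25,88.5,74,37.3,60,3076,98,0.428,92
44,101,45,138,102,37,11,83.0,24,37.5,57,3501,54,0.545,38
45,98,11,135,47,37,11,79.8,7,33.5,102,3419,64,0.505,58
46,100,31,132,10,33,95,86.0,47,33.6,101,3446,57,0.461,80
47,99,22,132,10,34,75,79.8,7,34.0,98,2840,105,0.390,102
48,98,11,133,15,35,52,80.8,11,34.5,90,3438,59,0.511,56
49,101,45,136,61,35,52,86.3,49,36.5,73,2696,108,0.361,107
50,98,11,134,23,36,25,85.3,37,31.0,111,2839,106,0.357,108
51,98,11,135,48,38,4,86.3,49,37.3,63,3613,40,0.566,30
52,97,5,133,16,36,25,93.0,94,34.5,89,3386,67,0.451,83
53,100,31,133,16,34,75,86.3,49,35.6,79,3253,83,0.448,85
54,99,22,132,10,33,95,85.3,37,36.9,70,3831,22,0.578,26
55,100,31,134,23,35,52,86.5,52,37.3,64,3839,21,0.584,23
56,99,22,138,103,39,1,89.8,81,35.3,81,4083,11,0.614,16
57,101,45,136,62,35,52,83.5,27,34.3,93,3434,60,0.481,72
58,103,75,137,86,34,75,85.0,35,37.7,53,3754,28,0.575,27
59,100,31,134,23,35,52,82.5,22,37.5,55,3157,94,0.462,79
60,107,110,138,104,31,110,81.5,14,38.5,43,2372,110,0.323,110
61,98,11,134,23,35,52,78.8,5,32.8,106,3014,100,0.423,93
62,100,31,136,62,37,11,84.5,30,34.7,88,3824,23,0.580,25
63,102,58,136,62,35,52,87.3,64,33.7,100,3354,75,0.448,86
64,98,11,132,10,35,52,89.0,76,44.6,4,3431,62,0.573,28
65,102,58,136,62,34,75,84.5,30,37.5,56,3383,68,0.487,66
66,98,11,131,2,33,95,85.8,44,37.4,59,3222,89,0.449,84
67,100,31,137,87,36,25,87.5,67,37.3,65,3542,49,0.524,48
68,98,11,134,24,36,25,86.8,58,33.3,103,3433,61,0.469,77
69,101,45,136,62,35,52,86.5,52,31.3,110,3399,66,0.433,91
70,102,58,136,63,34,75,87.3,64,37.5,58,3572,46,0.517,51
71,99,22,134,25,35,52,84.5,30,32.9,105,3109,96,0.407,98
72,102,58,136,63,34,75,79.8,7,39.4,30,3623,37,0.583,24
73,102,58,135,48,33,95,81.8,15,42.0,16,3504,53,0.572,29
74,103,75,135,48,32,105,80.5,10,42.6,11,3382,69,0.551,36
75,99,22,134,26,35,52,85.5,40,34.9,85,3573,45,0.513,55
76,99,22,134,27,35,52,86.8,58,36.6,72,3544,48,0.524,47
77,103,75,136,64,33,95,93.5,95,40.0,26,3541,50,0.499,60
78,104,97,136,65,32,105,86.5,52,39.1,33,3620,39,0.530,45
79,102,58,137,88,35,52,90.5,83,42.5,12,3234,86,0.498,61
80,103,75,137,88,35,52,87.0,61,43.1,9,3795,25,0.635,8
81,103,75,138,105,35,52,92.8,92,41.5,19,2959,103,0.412,97
82,102,58,138,106,36,25,92.5,91,43.7,8,3781,27,0.616,15
83,103,75,136,66,33,95,88.5,74,42.3,13,3239,85,0.483,69
84,104,97,137,88,34,75,84.5,30,43.7,7,3171,92,0.514,54
85,99,22,136,66,37,11,76.3,4,39.7,28,3445,58,0.598,20
86,101,45,134,28,33,95,75.0,3,38.0,48,4466,5,0.726,1
87,101,45,134,28,33,95,74.3,2,35.6,78,4281,7,0.677,5
88,100,31,135,48,35,52,87.5,67,34.0,97,3525,51,0.481,70
89,100,31,137,88,37,11,86.5,52,35.3,80,3661,36,0.538,44
90,102,58,137,89,35,52,87.8,70,37.3,62,3689,32,0.545,39
91,103,75,135,49,32,105,81.8,15,37.8,52,2198,111,0.317,111
92,105,104,136,67,32,105,88.0,71,37.3,61,3198,90,0.414,95
93,103,75,136,67,33,95,87.0,61,36.2,74,2993,101,0.378,104
94,103,75,134,29,32,105,88.0,71,37.9,51,3170,93,0.423,94
95,102,58,134,29,32,105,92.3,88,40.7,24,3608,43,0.528,46
96,102,58,134,29,33,95,92.0,87,39.5,29,3799,24,0.565,32
97,101,45,135,49,35,52,89.3,78,38.7,39,3972,15,0.623,13
98,103,75,138,107,35,52,92.3,88,35.7,77,3622,38,0.498,62
99,97,5,135,49,38,4,83.8,28,38.9,37,3878,20,0.656,7
100,103,75,136,68,34,75,100.8,108,39.2,32,3665,34,0.488,65
101,102,58,137,90,35,52,97.8,105,39.1,34,3550,47,0.487,68
102,100,31,134,29,34,75,107.8,110,42.0,17,3577,44,0.476,73
103,100,31,134,29,34,75,108.5,111,42.0,14,3664,35,0.487,67
104,101,45,135,50,34,75,97.0,104,36.9,69,3998,14,0.554,34
105,102,58,135,51,33,95,95.3,98,39.0,35,4598,3,0.662,6
106,103,75,136,68,33,95,95.8,100,40.9,22,3308,79,0.452,82
107,97,5,130,1,34,75,83.3,26,42.0,15,3288,80,0.538,43
108,106,108,137,91,31,110,85.1,36,40.8,23,4634,2,0.705,2
109,100,31,136,69,36,25,89.4,79,37.9,49,4006,13,0.626,12
110,107,110,139,111,33,95,81.3,13,41.4,20,3710,30,0.599,19
111,103,75,136,69,34,75,94.7,97,35.9,76,3784,26,0.510,57
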