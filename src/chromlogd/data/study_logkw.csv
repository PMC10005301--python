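compound_id,7.0,8.0,9.0,10.0
1,1.47,1.44,1.45,1.49
2,1.50,1.53,1.54,1.58
3,3.20,3.44,3.47,3.54
4,1.40,1.41,1.44,1.46
5,1.13,1.12,1.14,1.18
6,1.68,1.76,1.78,1.81
7,2.06,2.23,2.30,2.34
8,2.18,2.37,2.39,2.44
9,0.36,0.49,1.05,1.42
10,1.45,1.49,1.50,1.60
11,1.38,1.41,1.42,1.49
12,1.05,0.99,1.07,1.11
13,-0.39,-0.35,-0.17,-0.04
14,0.70,0.92,1.01,1.05
15,0.97,1.61,2.13,2.44
16,1.00,1.16,1.28,1.32
17,2.42,2.57,2.59,2.65
18,1.76,1.85,1.88,1.96
19,1.92,1.98,2.00,2.04
20,0.99,1.13,1.19,1.27
21,0.96,0.95,0.97,1.02
22,2.66,2.81,2.84,2.80
23,1.31,1.32,1.34,1.36
24,1.91,1.98,1.99,1.99
25,1.87,1.94,1.95,1.95
26,1.74,1.79,1.80,1.90
27,2.42,2.99,3.28,4.54
28,0.50,0.49,0.29,0.60
29,0.17,0.07,-0.16,0.21
30,1.76,1.79,1.46,1.84
31,1.80,1.86,1.78,1.92
32,2.07,2.13,2.14,2.18
33,2.19,2.25,2.26,2.30
34,-0.39,-0.38,-0.27,-0.15
35,0.80,0.66,0.82,0.88
36,1.36,1.36,1.38,1.43
37,1.18,1.18,1.20,1.30
38,1.36,1.36,1.38,1.43
39,2.22,2.28,2.29,2.28
40,-0.53,-0.39,-0.34,-0.16
41,-0.08,0.19,0.32,0.39
42,1.78,1.83,1.83,1.47
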