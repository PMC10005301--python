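compound_id,7.0,8.0,9.0,10.0
1,1.40,1.40,1.40,1.40
2,1.40,1.41,1.41,1.41
3,3.17,3.29,3.31,3.31
4,1.29,1.33,1.33,1.33
5,1.15,1.15,1.15,1.15
6,1.52,1.66,1.68,1.68
7,1.44,1.91,2.00,2.01
8,2.30,2.31,2.31,2.31
9,-1.26,-0.28,0.58,1.00
10,1.23,1.24,1.24,1.24
11,0.95,0.95,0.95,0.95
12,0.79,0.80,0.80,0.80
13,-0.38,-0.31,-0.30,-0.30
14,0.63,0.76,0.78,0.78
15,0.17,1.12,1.77,1.95
16,0.36,0.80,0.88,0.89
17,2.23,2.23,2.23,2.23
18,1.51,1.63,1.65,1.65
19,1.68,1.68,1.68,1.68
20,0.53,0.98,1.07,1.08
21,0.90,0.90,0.90,0.90
22,2.58,2.59,2.59,2.59
23,1.05,1.09,1.09,1.09
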