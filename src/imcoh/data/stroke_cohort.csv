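subject,sex,age_years,time_since_stroke_months,emnsa,fugl_meyer,stroke_type
1,M,61,51,27,38,ischemic
2,M,59,18,60,46,hemorrhagic
3,F,69,19,50,44,ischemic
4,M,65,75,50,32,hemorrhagic
5,M,50,30,60,42,ischemic
6,M,57,14,61,45,ischemic
7,M,75,26,56,26,ischemic
8,M,48,8,33,49,ischemic
9,M,65,116,54,30,ischemic
10,M,49,13,62,53,ischemic
11,F,33,9,63,45,ischemic
12,F,34,12,48,21,ischemic
13,M,57,18,52,41,ischemic
14,M,56,34,26,29,ischemic
15,M,76,12,60,50,ischemic
16,M,74,34,58,23,ischemic
17,M,67,6,63,47,ischemic
18,M,43,15,24,46,ischemic
19,M,72,43,39,36,hemorrhagic
20,M,41,15,41,58,ischemic
21,M,52,36,64,41,ischemic
22,M,54,12,23,27,hemorrhagic
23,F,39,52,64,63,ischemic
24,M,54,27,35,47,ischemic
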