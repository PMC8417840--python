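subject_id,group,age,sex,onset_age,n_aeds
4,WC,25,M,19,2
18,WC,24,F,16,3
23,WC,23,M,16,2
24,WC,19,F,13,1
26,WC,18,F,15,1
27,WC,22,M,2,1
29,WC,56,F,3,1
31,WC,33,M,7,1
32,WC,19,F,14,1
34,WC,20,M,16,2
1,DR,23,F,14,3
2,DR,19,M,16,1
3,DR,19,F,8,1
5,DR,60,F,13,1
6,DR,24,M,15,3
7,DR,21,F,15,2
8,DR,32,F,23,2
9,DR,38,M,18,2
10,DR,67,M,29,4
11,DR,46,F,7,3
13,DR,20,M,8,1
14,DR,24,F,13,1
15,DR,35,M,6,2
16,DR,18,M,14,2
17,DR,39,M,17,1
19,DR,21,M,16,1
20,DR,36,F,17,2
21,DR,31,F,15,2
22,DR,31,F,16,2
25,DR,58,F,15,3
28,DR,24,M,13,1
30,DR,57,F,7,2
33,DR,57,F,7,2
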