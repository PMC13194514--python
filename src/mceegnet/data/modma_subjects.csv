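id,type,gender,PHQ-9
1,MDD,F,23
2,MDD,F,12
3,MDD,M,19
4,MDD,M,16
5,MDD,M,17
6,MDD,M,19
7,MDD,M,24
8,MDD,F,22
9,MDD,F,11
10,MDD,M,14
11,MDD,F,18
12,MDD,M,19
13,MDD,F,21
14,MDD,F,20
15,MDD,M,18
16,MDD,F,16
17,MDD,F,23
18,MDD,M,20
19,MDD,M,15
20,MDD,M,17
21,MDD,F,24
22,MDD,F,19
23,MDD,M,16
24,MDD,M,17
25,HC,M,1
26,HC,M,4
27,HC,M,5
28,HC,F,3
29,HC,F,0
30,HC,M,3
31,HC,M,3
32,HC,M,3
33,HC,M,5
34,HC,M,4
35,HC,M,3
36,HC,M,0
37,HC,M,2
38,HC,M,2
39,HC,M,4
40,HC,M,5
41,HC,M,0
42,HC,M,5
43,HC,F,3
44,HC,F,0
45,HC,F,0
46,HC,F,0
47,HC,M,4
48,HC,F,3
49,HC,M,3
50,HC,M,3
51,HC,M,4
52,HC,F,5
53,HC,F,0
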