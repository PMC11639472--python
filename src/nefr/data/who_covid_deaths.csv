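value
6
15
57
1
4
66
1
6
2
14
6
4
35
6
3
5
187
6
92
2
21
3
32
30
5
110
1
3
3
35
14
128
6
34
1
1
16
6
3
9
10
7
1
38
6
9
43
27
18
734
93
33
22
6
140
4
2
356
9
15
523
232
3
1
1
38
19
9
3
11
32
1
11
11
48
38
3
13
8
4
22
15
28
10
7
8
54
4
65
243
62
3
30
8
4
11
1
44
32
149
94
3
1
9
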