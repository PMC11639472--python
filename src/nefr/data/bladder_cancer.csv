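value
21.73
4.4
7.93
7.39
8.26
4.34
8.37
3.48
7.63
2.83
9.74
3.25
0.81
10.66
11.98
14.76
5.32
0.5
3.57
13.11
34.26
1.26
1.19
2.02
4.5
0.51
7.09
7.28
2.23
2.69
4.18
26.31
2.62
12.02
2.54
0.2
3.31
5.49
4.33
5.32
0.08
1.46
25.74
5.62
6.76
7.87
5.85
7.62
20.28
5.41
2.07
5.17
3.82
17.14
16.62
22.69
11.64
0.4
14.24
4.23
6.97
3.02
8.53
11.25
15.96
6.25
5.06
4.51
3.88
13.29
3.36
10.34
2.75
2.64
9.47
5.41
1.35
6.94
0.9
2.09
11.79
17.36
7.32
32.15
5.71
9.02
13.8
10.06
1.05
19.13
79.05
6.93
14.83
3.52
17.12
5.09
8.65
2.69
2.26
12.03
3.64
7.66
36.66
1.76
23.63
12.07
2.02
3.36
10.75
9.22
2.46
14.77
25.82
4.87
6.54
12.63
8.66
5.34
4.98
1.4
7.26
3.7
46.12
18.1
43.01
2.87
7.59
4.26
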