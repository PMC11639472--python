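value
35
102
38
96
204
264
663
105
25
90
67
87
172
19
69
120
26
181
627
190
111
40
163
228
3
283
155
2
68
36
192
4
4
2
199
24
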