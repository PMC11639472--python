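scenario,n,mle,lse,wlse,ade
1,25,1.0,4.0,2.0,3.0
1,50,1.0,4.0,3.0,2.0
1,75,1.0,4.0,3.0,2.0
1,100,1.0,4.0,3.0,2.0
1,125,1.0,4.0,3.0,2.0
1,150,1.0,4.0,3.0,2.0
1,175,1.0,4.0,3.0,2.0
1,200,1.0,4.0,3.0,2.0
1,225,1.0,4.0,3.0,2.0
1,250,1.0,4.0,3.0,2.0
2,25,2.0,4.0,3.0,1.0
2,50,1.0,4.0,3.0,2.0
2,75,1.0,4.0,3.0,2.0
2,100,1.0,4.0,3.0,2.0
2,125,1.0,4.0,3.0,2.0
2,150,1.0,4.0,3.0,2.0
2,175,1.0,4.0,2.0,2.0
2,200,1.0,4.0,2.0,3.0
2,225,1.0,4.0,2.0,3.0
2,250,1.0,4.0,2.0,3.0
3,25,3.0,4.0,2.0,1.0
3,50,1.0,4.0,3.0,2.0
3,75,1.0,4.0,3.0,2.0
3,100,1.0,4.0,3.0,2.0
3,125,1.0,4.0,3.0,2.0
3,150,1.0,4.0,3.0,2.0
3,175,1.0,4.0,3.0,2.0
3,200,1.0,4.0,3.0,2.0
3,225,1.0,4.0,3.0,2.0
3,250,1.0,4.0,2.0,3.0
4,25,2.0,4.0,3.0,1.0
4,50,1.0,4.0,3.0,2.0
4,75,1.0,4.0,3.0,2.0
4,100,1.0,4.0,3.0,2.0
4,125,1.0,4.0,3.0,2.0
4,150,1.0,4.0,2.5,2.5
4,175,1.0,4.0,3.0,2.0
4,200,1.0,4.0,2.0,3.0
4,225,1.0,4.0,2.5,2.5
4,250,1.5,4.0,1.5,3.0
5,25,2.0,4.0,3.0,1.0
5,50,1.0,4.0,3.0,2.0
5,75,1.0,4.0,3.0,2.0
5,100,1.0,4.0,3.0,2.0
5,125,1.0,4.0,2.5,2.5
5,150,1.5,4.0,3.0,1.5
5,175,1.0,4.0,3.0,2.0
5,200,2.5,4.0,2.5,1.0
5,225,1.5,4.0,1.5,3.0
5,250,2.0,4.0,3.0,1.0
6,25,1.0,4.0,3.0,2.0
6,50,1.0,4.0,3.0,2.0
6,75,1.0,4.0,3.0,2.0
6,100,1.5,4.0,3.0,1.5
6,125,1.5,4.0,3.0,1.5
6,150,1.0,4.0,3.0,2.0
6,175,1.0,4.0,3.0,2.0
6,200,1.0,4.0,3.0,2.0
6,225,1.0,4.0,3.0,2.0
6,250,1.0,4.0,3.0,2.0
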