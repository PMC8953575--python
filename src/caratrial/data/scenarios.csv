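sc,beta0,beta1,beta2,gamma0,gamma1,gamma2
1,0,0,0,0,0,0
2,-0.5,0.5,0,0,0,0
3,-0.5,1,0,0,0,0
4,-1,0,0.5,0,0,0
5,-1,0,2,0,0,0
6,-0.5,0.5,0.5,0,0,0
7,-0.5,1,1,0,0,0
8,-0.5,-0.5,0.5,0,0,0
9,-0.5,-1,1,0,0,0
10,0,0,0,-0.5,0,0
11,-0.5,0.5,0,-0.5,0,0
12,-0.5,-0.2,0,-0.5,0,0
13,-0.5,0,0,-0.5,-0.5,0
14,-0.5,0,0,-0.5,0.5,0
15,-0.5,0.5,0,-0.5,-0.5,0
16,-1,0,0.5,-0.5,0,0
17,-1,0,2,-0.5,0,0
18,-1,0,2,-0.5,0,0.5
19,0.5,0.5,-0.5,-0.5,0.5,-0.5
20,0.5,0.5,-0.5,-0.65,0.5,0.5
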