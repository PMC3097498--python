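run,naoh,time,power,response
1,0.1,15,420,0
2,1,15,420,0
3,0.1,30,420,2
4,1,30,420,8
5,0.1,15,700,17
6,1,15,700,21
7,0.1,30,700,28
8,1,30,700,33
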