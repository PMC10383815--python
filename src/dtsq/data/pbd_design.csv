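run,M,DS,NS,TD,RG,D1,Temp
1,5,0,128,16384,40.3,2,300
2,5,8,16,65536,40.3,2,296
3,0.5,8,128,16384,161,2,296
4,5,0,128,65536,40.3,30,296
5,5,8,16,65536,161,2,300
6,5,8,128,16384,161,30,296
7,0.5,8,128,65536,40.3,30,300
8,0.5,0,128,65536,161,2,300
9,0.5,0,16,65536,161,30,296
10,5,0,16,16384,161,30,300
11,0.5,8,16,16384,40.3,30,300
12,0.5,0,16,16384,40.3,2,296
13,2,4,64,32768,90.5,10,298
14,2,4,64,32768,90.5,10,298
15,2,4,64,32768,90.5,10,298
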