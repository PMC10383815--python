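run,NS,TD,Tl,accuracy,snr,tq
1,32,32768,20,1.742,1314.49,13.68
2,32,98304,20,1.327,1270.59,13.68
3,80,32768,20,1.567,1904.43,31.93
4,80,98304,20,0.947,1908.12,31.93
5,32,32768,30,0.785,1225.88,19.68
6,32,98304,30,0.396,1217.23,19.68
7,80,32768,30,0.186,2006.74,45.93
8,80,98304,30,0.037,2010.88,45.93
9,56,16384,25,2.161,1621.74,27.80
10,56,131072,25,0.066,1678.88,27.80
11,16,65536,25,1.238,843.20,9.27
12,96,65536,25,0.130,2215.89,46.35
13,56,65536,16.59,1.830,1689.57,19.40
14,56,65536,33.41,0.049,1609.00,36.22
15,56,65536,25,0.723,1577.34,27.80
16,56,65536,25,0.623,1637.77,27.80
17,56,65536,25,0.718,1652.33,27.80
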