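run,accuracy,snr,resolution
1,77.07,2446.8,0.71
2,17.65,1316.0,0.62
3,55.75,1601.0,1.35
4,0.291,4174.4,0.68
5,27.69,1343.4,0.61
6,0.709,2771.8,1.29
7,0.411,3407.8,0.96
8,23.07,3404.6,0.75
9,0.747,1660.5,0.72
10,9.572,1589.5,0.72
11,4.133,965.6,1.36
12,51.68,658.6,1.15
13,6.202,3288.7,0.63
14,6.055,3451.9,0.60
15,6.263,3318.1,0.60
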