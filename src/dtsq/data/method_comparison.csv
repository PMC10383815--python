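batch,uv,qnmr,relative_deviation
1,36.45,36.53,-0.21
2,39.56,41.12,-3.78
3,43.07,42.26,1.92
4,40.86,41.80,-2.25
5,38.94,40.80,-4.55
6,36.45,36.68,-0.61
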