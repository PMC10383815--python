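term,accuracy,snr,tq
b0,0.855,1633.050,27.802
X1,-0.228,345.696,10.240
X2,-0.338,,
X3,-0.485,-4.90011,4.619
X1^2,,-29.765,0.002
X3^2,,,0.002
X1*X3,,36.901,1.701
r2,0.853,0.988,1.000
r2_adj,0.819,0.983,1.000
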