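gene,AntA,AntB,AntC,Atlantic,Offshore,Resident,Transient,AntB+AntC,cov
COX1,0.99,0,0,0.11,0.87,0,0.99,1,1.0
ND4,0.56,0,0,0,0,0.99,0.93,0.96,5.58
CYTB,0.99,1,0,0.99,0,0,0.99,0,0.73
ND1,0.67,0,0,0.92,0,0,0.22,0.98,0.66
ND3,0,0.62,0.94,0,0,0,0.53,0.9,4.18
CR,0.59,0,0,0,0,0,0.69,1,0.3
12S16S,0.67,0,0,0,0,0,0.55,0.98,7.52
ATP8,0,0,0,0,0,0.99,0.94,0,6.41
COX3,0,0,0,0,0,0,0.9,0.98,4.69
ATP6,0,0,0,0,0,0.99,0.92,0,5.27
ND4L,0,0,0,0,0,0,0.92,0.97,5.54
ND2,0.77,0,0,0,0,0,0.93,0,5.55
ND5,0.06,0,0,0.08,0.08,0,0.21,0.98,4.91
COX2,0,0,0,0,0,0,0.68,0,5.52
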