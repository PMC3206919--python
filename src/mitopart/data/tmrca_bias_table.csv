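node,partition,median_tmrca,hpd_low,hpd_high,bias
Transient,12S16S,0.37,0.13,0.72,0.92
Transient,ND1,0.64,0.35,0.94,0.87
Transient,ND2,0.36,0.13,0.71,0.92
Transient,COX1,0.31,0.13,0.54,0.66
Transient,COX2,0.39,0.15,0.73,0.95
Transient,ATP8,0.41,0.17,0.76,0.94
Transient,ATP6,0.39,0.15,0.73,0.92
Transient,COX3,0.41,0.17,0.77,0.97
Transient,ND3,0.49,0.20,0.85,0.94
Transient,ND4L,0.41,0.16,0.78,0.98
Transient,ND4,0.39,0.15,0.73,0.87
Transient,ND5,0.40,0.16,0.76,0.75
Transient,CYTB,0.32,0.14,0.58,0.78
Transient,CR,0.32,0.14,0.55,0.78
Transient,"COX1,ND3,ATP6,CYTB",0.23,0.10,0.41,0.51
Transient,mitogenome,0.20,0.06,0.45,0.50
Globicephalinae,12S16S,12.13,8.89,14.33,0.88
Globicephalinae,ND1,8.11,5.96,10.65,0.74
Globicephalinae,ND2,6.74,4.94,8.88,0.57
Globicephalinae,COX1,7.36,5.50,9.33,0.60
Globicephalinae,COX2,9.05,6.11,12.50,0.84
Globicephalinae,ATP8,6.29,3.54,10.17,0.73
Globicephalinae,ATP6,10.71,7.18,10.50,0.75
Globicephalinae,COX3,8.33,5.71,11.33,0.82
Globicephalinae,ND3,12.20,8.39,14.48,0.95
Globicephalinae,ND4L,10.63,6.70,13.90,0.90
Globicephalinae,ND4,7.42,5.74,9.36,0.59
Globicephalinae,ND5,8.06,6.28,9.90,0.72
Globicephalinae,CYTB,6.70,4.75,8.74,0.63
Globicephalinae,CR,8.32,5.83,12.70,0.85
Globicephalinae,"ND1,COX1,ND4",7.81,6.48,9.36,0.44
Globicephalinae,mitogenome,8.07,6.94,9.25,0.50
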