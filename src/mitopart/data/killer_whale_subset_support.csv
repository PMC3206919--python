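clade,pp
AntA,1
AntB,1
AntC,1
Atlantic,1
Offshore,1
Resident,1
Transient,0.99
AntB+AntC,1
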