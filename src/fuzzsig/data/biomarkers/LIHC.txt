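AFP
DKK1
VEGFA
IGF1
IL6
CXCR2
CCR2
EP400
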