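APOD
CDKL2
CLEC4F
CSF2
HAPLN1
ITIH2
KLHDC8A
KLK13
MMP23A
MYOC
R3HDML
RBP4
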