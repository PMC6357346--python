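ESR1
ERBB2
MKI67
CCND1
CCNE1
ESR2
BRCA1
BRCA2
PGR
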