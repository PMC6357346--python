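AMDHD1
AMY2B
AQP5
C17orf102
C19orf45
CHST4
GABRR1
GCKR
HSD17B3
IL17A
LTK
OVCH2
PTCHD3
PTGS2
RPL10L
SEPT12
SOX8
TRH
TYR
UGT2B10
UGT3A1
VSIG10L
ZNHIT2
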