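ABCA4
AFAP1L2
ALDOB
ASPG
B3GALT2
BIRC5
C17orf78
CA9
CCNI2
CDKN2A
CHP2
CLDN19
ENOX1
FOXD2
GINS2
GREM2
INSRR
KIFC2
KNG1
MET
MUC15
MYOM1
NOTUM
PLIN2
PTCHD3
SFRP1
SIAH3
SPRR2A
ST6GALNAC3
VEGFA
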