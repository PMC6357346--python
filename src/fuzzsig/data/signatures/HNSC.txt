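ALG1L
BOC
CA13
CLDN10
CMA1
CNTFR
DIXDC1
FGFR2
FOXS1
GBX2
GPT
HCN1
HOXC6
HOXC9
HOXD10
HOXD9
HPR
KALRN
KIR2DS4
LAIR2
LPPR5
MARCH4
MMP13
PAEP
PCDHGA9
PCDHGB7
PCK1
PHGDH
PIK3R1
PTCHD3
RIMS4
SCIN
SDPR
SLC46A2
SLC5A8
SORBS2
SOX11
SPP1
SRD5A2
SVIP
TAC1
TGFBR3
TMEM132C
TMEM217
TRPC4
ZIC5
ZNF132
ZNF43
ZNF486
ZNF608
ZNF626
ZNF677
ZNF813
ZNF844
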