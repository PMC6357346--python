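ABCB5
ADAMTS5
ALX4
ANPEP
APCDD1
ARHGAP20
BCHE
BRCA2
CCL11
CCL28
CDKN2A
CEBPA
CHRNA6
CNN1
COL6A6
CX3CL1
DNAH14
EMILIN2
ERBB2
FGF10
GRID1
GSN
HTR2A
KCNJ2
KCNMB1
KLB
KRT4
LEP
LOXL1
LRIT2
MYOC
NRN1
OLFM3
OR10A3
OXTR
P4HA3
PENK
PRSS55
PSG3
RAX2
RPE65
SH3TC2
TBX15
TPO
VGLL2
WISP1
WT1
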