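ADCYAP1R1
AMPD1
ANKRD34A
ANKRD34C
B3GALT5
B4GALNT1
C1orf177
CASQ2
CCL19
CD207
CDH13
CDKN2A
CSPG4
DMC1
EBF2
ECM1
ELAVL2
EPO
FHL5
GJA1
GJC1
GLYATL2
GOLGA8A
GYPA
HBB
HBD
HSF4
HSPG2
IFITM4P
IL20RA
IL20RB
IRX3
LCE2D
MARCH4
MKRN3
NPAS4
NRXN1
OR51E2
PCSK2
PDZD2
PKMYT1
PMP2
RBM11
SEMA5B
SFTA1P
SLC17A8
SLCO1C1
STC2
TAC1
TM4SF18
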