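LGALS3
MET
BRAF
RET
HRAS
PAX8
PPARG
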