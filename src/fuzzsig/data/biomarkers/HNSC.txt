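CCR7
CD44
CEP55
CTTN
CXCR4
MMP2
NFKB1
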