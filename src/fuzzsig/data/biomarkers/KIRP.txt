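VHL
STC2
VCAN
VEGFA
CA9
VCAM1
HIF1A
BIRC5
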