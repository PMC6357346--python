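cancer	n_deg	n_dmg_expanded	n_dmg_original
BRCA	1702	2480	2275
PRAD	901	2516	2233
LIHC	1665	3315	3009
HNSC	1417	2845	2700
KIRP	2192	1738	1521
THCA	1319	1053	569
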