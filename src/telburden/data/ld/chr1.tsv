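RS_number	rs621559	rs3219104	rs1805087
rs621559	1
rs3219104	0	1
rs1805087	0.001	0	1
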