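RS_number	rs1001761	rs2162440	rs7235755
rs1001761	1
rs2162440	0	1
rs7235755	0	1	1
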