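RS_number	rs10046	rs2899470	rs700518
rs10046	1
rs2899470	0.880	1
rs700518	0.837	0.746	1
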