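RS_number	rs12299470	rs2630578	rs1151026	rs17653722
rs12299470	1
rs2630578	0.006	1
rs1151026	0.004	0.860	1
rs17653722	0	0	0	1
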