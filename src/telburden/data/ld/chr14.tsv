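RS_number	rs938886	rs4246977	rs41293836	rs1483898	rs398652	rs2302588	rs2535913
rs938886	1
rs4246977	0.005	1
rs41293836	0.004	0.008	1
rs1483898	0	0	0	1
rs398652	0.003	0.001	0	0.001	1
rs2302588	0.001	0	0.001	0.001	0.001	1
rs2535913	0	0	0	0	0	0.058	1
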