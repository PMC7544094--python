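RS_number	rs669976	rs524386	rs2957154	rs670358	rs660339	rs659366	rs12270338	rs13447720	rs228595	rs1801516	rs227080
rs669976	1
rs524386	0.688	1
rs2957154	0.005	0.018	1
rs670358	0.155	0.211	0.001	1
rs660339	0.001	0.003	0	0.001	1
rs659366	0.001	0.003	0.001	0.001	0.822	1
rs12270338	0.002	0	0.002	0.004	0.002	0.002	1
rs13447720	0.001	0	0.001	0.006	0.002	0.002	0.948	1
rs228595	0	0	0.004	0.007	0	0	0	0	1
rs1801516	0	0.001	0	0	0	0	0	0	0.161	1
rs227080	0	0	0.006	0.003	0.001	0	0	0	0.460	0.127	1
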