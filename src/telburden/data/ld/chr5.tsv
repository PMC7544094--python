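RS_number	rs2075786	rs10054203	rs7726159	rs7705526	rs2736100	rs2853677	rs2736108	rs401681	rs2966952	rs3733890
rs2075786	1
rs10054203	0.02	1
rs7726159	0.047	0.607	1
rs7705526	0.023	0.454	0.788	1
rs2736100	0.003	0.316	0.516	0.510	1
rs2853677	0	0.061	0.181	0.185	0.435	1
rs2736108	0.014	0.001	0.015	0.042	0.149	0.220	1
rs401681	0.016	0.013	0.003	0	0.004	0.014	0.174	1
rs2966952	0	0.001	0	0.001	0	0	0.001	0.001	1
rs3733890	0.002	0	0	0.001	0.001	0.001	0.001	0	0	1
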