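RS_number	rs6772228	rs55749605	rs12638862	rs12696304	rs2293607	rs10936599	rs1317082	rs3772190	rs10936600	rs16847897	rs1920116
rs6772228	1
rs55749605	0	1
rs12638862	0	0.001	1
rs12696304	0	0.002	0.945	1
rs2293607	0	0.001	0.933	0.881	1
rs10936599	0	0	0.928	0.876	0.995	1
rs1317082	0	0	0.928	0.876	0.995	1	1
rs3772190	0	0	0.928	0.876	0.995	1	1	1
rs10936600	0	0	0.928	0.876	0.995	1	1	1	1
rs16847897	0	0.001	0.479	0.458	0.524	0.528	0.528	0.528	0.528	1
rs1920116	0	0.001	0.479	0.452	0.524	0.528	0.528	0.528	0.528	0.990	1
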