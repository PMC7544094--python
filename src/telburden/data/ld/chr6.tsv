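RS_number	rs34991172	rs1800629	rs2736176	rs558702	rs654128
rs34991172	1
rs1800629	0.098	1
rs2736176	0.012	0.035	1
rs558702	0.140	0.450	0.035	1
rs654128	0.003	0.001	0.001	0.003	1
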