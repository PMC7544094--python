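RS_number	rs10466239	rs7095953	rs7100920	rs2067832	rs10786775	rs2487999	rs9419958	rs9420907	rs4387287	rs12415148
rs10466239	1
rs7095953	0	1
rs7100920	0	0	1
rs2067832	0	0	0.996	1
rs10786775	0	0	0.113	0.117	1
rs2487999	0	0	0.113	0.117	1	1
rs9419958	0	0.001	0.17	0.174	0.639	0.639	1
rs9420907	0	0.001	0.17	0.174	0.639	0.639	1	1
rs4387287	0.001	0.001	0.108	0.111	0.525	0.525	0.822	0.822	1
rs12415148	0.015	0.004	0.009	0.009	0.001	0.001	0.002	0.002	0.002	1
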