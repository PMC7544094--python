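RS_number	rs13137667	rs7680468	rs7675998	rs4691895	rs10857352
rs13137667	1
rs7680468	0.001	1
rs7675998	0.001	0	1
rs4691895	0.001	0	0.967	1
rs10857352	0.005	0	0.203	0.207	1
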