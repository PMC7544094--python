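RS_number	rs3027234	rs78148049	rs820152
rs3027234	1
rs78148049	0	1
rs820152	0	0	1
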