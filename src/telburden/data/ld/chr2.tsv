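RS_number	rs11125529	rs11890390
rs11125529	1
rs11890390	0.951	1
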