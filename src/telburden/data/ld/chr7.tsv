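RS_number	rs59294613	rs7776744
rs59294613	1
rs7776744	0.249	1
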