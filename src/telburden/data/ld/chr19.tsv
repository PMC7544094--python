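RS_number	rs8105767	rs7253490	rs412658
rs8105767	1
rs7253490	0.821	1
rs412658	0.534	0.603	1
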