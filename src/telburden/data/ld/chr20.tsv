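RS_number	rs6028466	rs73598374	rs75691080	rs34978822	rs41309367	rs6010620	rs2297439	rs755017	rs73624724
rs6028466	1
rs73598374	0	1
rs75691080	0.001	0	1
rs34978822	0.001	0	0.001	1
rs41309367	0	0.001	0.042	0.029	1
rs6010620	0	0.001	0.026	0.047	0.621	1
rs2297439	0	0	0.518	0.001	0.039	0.025	1
rs755017	0.001	0.001	0.013	0	0.204	0.090	0.011	1
rs73624724	0.001	0.003	0.006	0	0.180	0.077	0.004	0.913	1
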