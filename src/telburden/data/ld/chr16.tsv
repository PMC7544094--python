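RS_number	rs17817449	rs9939609	rs74019828	rs3785074	rs62053580	rs7194734	rs2967374
rs17817449	1
rs9939609	0.996	1
rs74019828	0.002	0.002	1
rs3785074	0.001	0.001	0.001	1
rs62053580	0	0	0.001	0	1
rs7194734	0	0	0.001	0	0.001	1
rs2967374	0	0	0.002	0	0.001	0.954	1
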