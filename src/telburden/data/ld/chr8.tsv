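RS_number	rs11991621	rs6990097	rs12549064	rs10903314	rs6990300	rs11249943	rs17150478	rs28365964
rs11991621	1
rs6990097	0.531	1
rs12549064	0.808	0.568	1
rs10903314	0.565	0.747	0.585	1
rs6990300	0.395	0.518	0.410	0.696	1
rs11249943	0.683	0.421	0.705	0.537	0.468	1
rs17150478	0.651	0.378	0.662	0.488	0.404	0.763	1
rs28365964	NA	NA	NA	NA	NA	NA	NA	NA
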