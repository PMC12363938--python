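pair_kind	gene_a	gene_b	n_nmd_members	source
bicistronic	SYN0004	SYN0008	2	synthetic
bicistronic	SYN0013	SYN0019	2	synthetic
bicistronic	SYN0033	SYN0059	2	synthetic
pseudogene	SYN0015	SYN0018	2	synthetic
pseudogene	SYN0048	SYN0053	2	synthetic
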