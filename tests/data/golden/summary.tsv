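category	n_genes
uORF_extended_LUTI	8
uORF_short_leader	8
IIT	8
ITI	8
retained_intron	6
long_3UTR	6
pseudo_bicistronic	6
pseudogene	4
unexplained	0
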