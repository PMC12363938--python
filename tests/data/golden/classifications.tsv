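gene_id	nmd_via	leader_class	orf_class	rationalization	has_leader_peaks	has_orf_peaks	main_start_peak	split_positive	long_utr3	bicistronic_member	pseudogene_member	retained_intron
SYN0001	orf_de	none	none	long_3UTR	False	False	True	False	True	False	False	False
SYN0002	intron_de	none	none	retained_intron	False	False	True	False	False	False	False	True
SYN0003	orf_de	none	ITI	ITI	False	True	False	True	False	False	False	False
SYN0004	orf_de	none	none	pseudo_bicistronic	False	False	True	False	False	True	False	False
SYN0005	orf_de	none	IIT	IIT	False	True	True	False	False	False	False	False
SYN0006	intron_de	none	none	retained_intron	False	False	True	False	False	False	False	True
SYN0007	intron_de	none	none	retained_intron	False	False	True	False	False	False	False	True
SYN0008	orf_de	none	none	pseudo_bicistronic	False	False	True	False	False	True	False	False
SYN0010	orf_de	short_5p_utr	none	uORF_short_leader	True	False	True	False	False	False	False	False
SYN0012	orf_de	none	IIT	IIT	False	True	True	False	False	False	False	False
SYN0013	orf_de	none	none	pseudo_bicistronic	False	False	True	False	False	True	False	False
SYN0014	orf_de	extended_5p	none	uORF_extended_LUTI	True	False	True	False	False	False	False	False
SYN0015	orf_de	none	none	pseudogene	False	False	True	False	False	False	True	False
SYN0016	orf_de	short_5p_utr	none	uORF_short_leader	True	False	True	False	False	False	False	False
SYN0017	intron_de	none	none	retained_intron	False	False	True	False	False	False	False	True
SYN0018	orf_de	none	none	pseudogene	False	False	True	False	False	False	True	False
SYN0019	orf_de	none	none	pseudo_bicistronic	False	False	True	False	False	True	False	False
SYN0020	orf_de	short_5p_utr	none	uORF_short_leader	True	False	True	False	False	False	False	False
SYN0021	orf_de	none	ITI	ITI	False	True	False	True	False	False	False	False
SYN0022	orf_de	none	IIT	IIT	False	True	True	False	False	False	False	False
SYN0023	orf_de	none	ITI	ITI	False	True	False	True	False	False	False	False
SYN0024	orf_de	extended_5p	none	uORF_extended_LUTI	True	False	True	False	False	False	False	False
SYN0026	orf_de	short_5p_utr	none	uORF_short_leader	True	False	True	False	False	False	False	False
SYN0027	orf_de	none	ITI	ITI	False	True	False	True	False	False	False	False
SYN0028	orf_de	none	IIT	IIT	False	True	True	False	False	False	False	False
SYN0029	intron_de	none	none	retained_intron	False	False	True	False	False	False	False	True
SYN0030	orf_de	none	none	long_3UTR	False	False	True	False	True	False	False	False
SYN0031	orf_de	short_5p_utr	none	uORF_short_leader	True	False	True	False	False	False	False	False
SYN0032	orf_de	extended_5p	none	uORF_extended_LUTI	True	False	True	False	False	False	False	False
SYN0033	orf_de	none	none	pseudo_bicistronic	False	False	True	False	False	True	False	False
SYN0034	orf_de	none	none	long_3UTR	False	False	True	False	True	False	False	False
SYN0035	intron_de	none	none	retained_intron	False	False	True	False	False	False	False	True
SYN0036	orf_de	short_5p_utr	none	uORF_short_leader	True	False	True	False	False	False	False	False
SYN0037	orf_de	none	none	long_3UTR	False	False	True	False	True	False	False	False
SYN0038	orf_de	none	ITI	ITI	False	True	False	True	False	False	False	False
SYN0039	orf_de	none	ITI	ITI	False	True	False	True	False	False	False	False
SYN0040	orf_de	none	ITI	ITI	False	True	False	True	False	False	False	False
SYN0042	orf_de	extended_5p	none	uORF_extended_LUTI	True	False	True	False	False	False	False	False
SYN0043	orf_de	none	IIT	IIT	False	True	True	False	False	False	False	False
SYN0045	orf_de	none	none	long_3UTR	False	False	True	False	True	False	False	False
SYN0048	orf_de	none	none	pseudogene	False	False	True	False	False	False	True	False
SYN0049	orf_de	extended_5p	none	uORF_extended_LUTI	True	False	True	False	False	False	False	False
SYN0050	orf_de	short_5p_utr	none	uORF_short_leader	True	False	True	False	False	False	False	False
SYN0051	orf_de	none	IIT	IIT	False	True	True	False	False	False	False	False
SYN0053	orf_de	none	none	pseudogene	False	False	True	False	False	False	True	False
SYN0054	orf_de	extended_5p	none	uORF_extended_LUTI	True	False	True	False	False	False	False	False
SYN0055	orf_de	extended_5p	none	uORF_extended_LUTI	True	False	True	False	False	False	False	False
SYN0056	orf_de	none	IIT	IIT	False	True	True	False	False	False	False	False
SYN0058	orf_de	extended_5p	none	uORF_extended_LUTI	True	False	True	False	False	False	False	False
SYN0059	orf_de	none	none	pseudo_bicistronic	False	False	True	False	False	True	False	False
SYN0060	orf_de	short_5p_utr	none	uORF_short_leader	True	False	True	False	False	False	False	False
SYN0061	orf_de	none	none	long_3UTR	False	False	True	False	True	False	False	False
SYN0062	orf_de	none	IIT	IIT	False	True	True	False	False	False	False	False
SYN0064	orf_de	none	ITI	ITI	False	True	False	True	False	False	False	False
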