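gene_id	nmd_via	retained_intron
SYN0001	orf_de	False
SYN0002	intron_de	True
SYN0003	orf_de	False
SYN0004	orf_de	False
SYN0005	orf_de	False
SYN0006	intron_de	True
SYN0007	intron_de	True
SYN0008	orf_de	False
SYN0010	orf_de	False
SYN0012	orf_de	False
SYN0013	orf_de	False
SYN0014	orf_de	False
SYN0015	orf_de	False
SYN0016	orf_de	False
SYN0017	intron_de	True
SYN0018	orf_de	False
SYN0019	orf_de	False
SYN0020	orf_de	False
SYN0021	orf_de	False
SYN0022	orf_de	False
SYN0023	orf_de	False
SYN0024	orf_de	False
SYN0026	orf_de	False
SYN0027	orf_de	False
SYN0028	orf_de	False
SYN0029	intron_de	True
SYN0030	orf_de	False
SYN0031	orf_de	False
SYN0032	orf_de	False
SYN0033	orf_de	False
SYN0034	orf_de	False
SYN0035	intron_de	True
SYN0036	orf_de	False
SYN0037	orf_de	False
SYN0038	orf_de	False
SYN0039	orf_de	False
SYN0040	orf_de	False
SYN0042	orf_de	False
SYN0043	orf_de	False
SYN0045	orf_de	False
SYN0048	orf_de	False
SYN0049	orf_de	False
SYN0050	orf_de	False
SYN0051	orf_de	False
SYN0053	orf_de	False
SYN0054	orf_de	False
SYN0055	orf_de	False
SYN0056	orf_de	False
SYN0058	orf_de	False
SYN0059	orf_de	False
SYN0060	orf_de	False
SYN0061	orf_de	False
SYN0062	orf_de	False
SYN0064	orf_de	False
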