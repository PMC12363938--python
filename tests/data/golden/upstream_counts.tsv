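gene_id	raw_upf1	raw_wt	truncated
SYN0001	480	120	False
SYN0002	120	120	False
SYN0003	0	0	False
SYN0004	480	120	False
SYN0005	480	120	False
SYN0006	120	120	False
SYN0007	120	120	False
SYN0008	480	120	False
SYN0010	480	120	False
SYN0012	480	120	False
SYN0013	480	120	False
SYN0014	480	120	False
SYN0015	480	120	False
SYN0016	480	120	False
SYN0017	120	120	False
SYN0018	480	120	False
SYN0019	480	120	False
SYN0020	480	120	False
SYN0021	0	0	False
SYN0022	480	120	False
SYN0023	0	0	False
SYN0024	480	120	False
SYN0026	480	120	False
SYN0027	0	0	False
SYN0028	480	120	False
SYN0029	120	120	False
SYN0030	480	120	False
SYN0031	480	120	False
SYN0032	480	120	False
SYN0033	480	120	False
SYN0034	480	120	False
SYN0035	120	120	False
SYN0036	480	120	False
SYN0037	480	120	False
SYN0038	0	0	False
SYN0039	0	0	False
SYN0040	0	0	False
SYN0042	480	120	False
SYN0043	480	120	False
SYN0045	480	120	False
SYN0048	480	120	False
SYN0049	480	120	False
SYN0050	480	120	False
SYN0051	480	120	False
SYN0053	480	120	False
SYN0054	480	120	False
SYN0055	480	120	False
SYN0056	480	120	False
SYN0058	480	120	False
SYN0059	480	120	False
SYN0060	480	120	False
SYN0061	480	120	False
SYN0062	480	120	False
SYN0064	0	0	False
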