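gene_id	first	last	ratio	is_split_positive	flags
SYN0001	800	800	1	False	.
SYN0002	200	200	1	False	.
SYN0003	0	800		True	ratio_undefined
SYN0004	800	800	1	False	.
SYN0005	800	800	1	False	.
SYN0006	200	200	1	False	.
SYN0007	200	200	1	False	.
SYN0008	800	800	1	False	.
SYN0010	800	800	1	False	.
SYN0012	800	800	1	False	.
SYN0013	800	800	1	False	.
SYN0014	800	800	1	False	.
SYN0015	800	800	1	False	.
SYN0016	800	800	1	False	.
SYN0017	200	200	1	False	.
SYN0018	800	800	1	False	.
SYN0019	800	800	1	False	.
SYN0020	800	800	1	False	.
SYN0021	0	800		True	ratio_undefined
SYN0022	800	800	1	False	.
SYN0023	0	800		True	ratio_undefined
SYN0024	800	800	1	False	.
SYN0026	800	800	1	False	.
SYN0027	0	800		True	ratio_undefined
SYN0028	800	800	1	False	.
SYN0029	200	200	1	False	.
SYN0030	800	800	1	False	.
SYN0031	800	800	1	False	.
SYN0032	800	800	1	False	.
SYN0033	800	800	1	False	.
SYN0034	800	800	1	False	.
SYN0035	200	200	1	False	.
SYN0036	800	800	1	False	.
SYN0037	800	800	1	False	.
SYN0038	0	800		True	ratio_undefined
SYN0039	0	800		True	ratio_undefined
SYN0040	0	800		True	ratio_undefined
SYN0042	800	800	1	False	.
SYN0043	800	800	1	False	.
SYN0045	800	800	1	False	.
SYN0048	800	800	1	False	.
SYN0049	800	800	1	False	.
SYN0050	800	800	1	False	.
SYN0051	800	800	1	False	.
SYN0053	800	800	1	False	.
SYN0054	800	800	1	False	.
SYN0055	800	800	1	False	.
SYN0056	800	800	1	False	.
SYN0058	800	800	1	False	.
SYN0059	800	800	1	False	.
SYN0060	800	800	1	False	.
SYN0061	800	800	1	False	.
SYN0062	800	800	1	False	.
SYN0064	0	800		True	ratio_undefined
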