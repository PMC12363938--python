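gene_id	genomic_pos	region	motif	frame	distance_to_main_start	score	height	flags
SYN0001	1057	orf	stop_UAA	0	297		0	annotation_only,below_threshold,zero_window
SYN0002	2352	orf	stop_UAA	0	297		0	annotation_only,below_threshold,zero_window
SYN0003	3611	orf	start_AUG	1	151	40.4	2740	.
SYN0003	3757	orf	stop_UAA	0	297		0	annotation_only,below_threshold,zero_window
SYN0004	4542	orf	stop_UAA	0	297		0	annotation_only,below_threshold,zero_window
SYN0005	5711	orf	start_AUG	1	151	40.4	2740	.
SYN0005	5857	orf	stop_UAA	0	297		0	annotation_only,below_threshold,zero_window
SYN0006	6642	orf	stop_UAA	0	297		0	annotation_only,below_threshold,zero_window
SYN0007	8137	orf	stop_UAA	0	297		0	annotation_only,below_threshold,zero_window
SYN0008	8922	orf	stop_UAA	0	297		0	annotation_only,below_threshold,zero_window
SYN0010	11367	leader	start_AUG	0	-48	13.4667	460	.
SYN0010	11358	leader	stop_UAA	0	-39	13.4667	460	annotation_only
SYN0010	11022	orf	stop_UAA	0	297		0	annotation_only,below_threshold,zero_window
SYN0012	13267	orf	start_AUG	2	152	40.4	2740	.
SYN0012	13122	orf	stop_UAA	0	297		0	annotation_only,below_threshold,zero_window
SYN0013	14437	orf	stop_UAA	0	297		0	annotation_only,below_threshold,zero_window
SYN0014	15770	leader	start_AUG	1	-251	20.2	460	.
SYN0014	15761	leader	stop_UAA	1	-242	20.2	460	annotation_only
SYN0014	15222	orf	stop_UAA	0	297		0	annotation_only,below_threshold,zero_window
SYN0015	16537	orf	stop_UAA	0	297		0	annotation_only,below_threshold,zero_window
SYN0016	17667	leader	start_AUG	0	-48	13.4667	460	.
SYN0016	17658	leader	stop_UAA	0	-39	13.4667	460	annotation_only
SYN0016	17322	orf	stop_UAA	0	297		0	annotation_only,below_threshold,zero_window
SYN0017	18727	orf	stop_UAA	0	297		0	annotation_only,below_threshold,zero_window
SYN0018	19512	orf	stop_UAA	0	297		0	annotation_only,below_threshold,zero_window
SYN0019	20827	orf	stop_UAA	0	297		0	annotation_only,below_threshold,zero_window
SYN0020	21958	leader	start_AUG	2	-49	13.931	460	.
SYN0020	21949	leader	stop_UAA	2	-40	13.4667	460	annotation_only
SYN0020	21612	orf	stop_UAA	0	297		0	annotation_only,below_threshold,zero_window
SYN0021	22781	orf	start_AUG	1	151	40.4	2740	.
SYN0021	22927	orf	stop_UAA	0	297		0	annotation_only,below_threshold,zero_window
SYN0022	23857	orf	start_AUG	2	152	40.4	2740	.
SYN0022	23712	orf	stop_UAA	0	297		0	annotation_only,below_threshold,zero_window
SYN0023	24881	orf	start_AUG	1	151	40.4	2740	.
SYN0023	25027	orf	stop_UAA	0	297		0	annotation_only,below_threshold,zero_window
SYN0024	26361	leader	start_AUG	0	-252	20.2	460	.
SYN0024	26352	leader	stop_UAA	0	-243	20.2	460	annotation_only
SYN0024	25812	orf	stop_UAA	0	297		0	annotation_only,below_threshold,zero_window
SYN0026	28258	leader	start_AUG	2	-49	13.931	460	.
SYN0026	28249	leader	stop_UAA	2	-40	13.4667	460	annotation_only
SYN0026	27912	orf	stop_UAA	0	297		0	annotation_only,below_threshold,zero_window
SYN0027	29081	orf	start_AUG	1	151	40.4	2740	.
SYN0027	29227	orf	stop_UAA	0	297		0	annotation_only,below_threshold,zero_window
SYN0028	30157	orf	start_AUG	2	152	40.4	2740	.
SYN0028	30012	orf	stop_UAA	0	297		0	annotation_only,below_threshold,zero_window
SYN0029	31417	orf	stop_UAA	0	297		0	annotation_only,below_threshold,zero_window
SYN0030	32712	orf	stop_UAA	0	297		0	annotation_only,below_threshold,zero_window
SYN0031	33682	leader	start_AUG	0	-48	13.4667	460	.
SYN0031	33691	leader	stop_UAA	0	-39	13.4667	460	annotation_only
SYN0031	34027	orf	stop_UAA	0	297		0	annotation_only,below_threshold,zero_window
SYN0032	35360	leader	start_AUG	1	-251	20.2	460	.
SYN0032	35351	leader	stop_UAA	1	-242	20.2	460	annotation_only
SYN0032	34812	orf	stop_UAA	0	297		0	annotation_only,below_threshold,zero_window
SYN0033	1057	orf	stop_UAA	0	297		0	annotation_only,below_threshold,zero_window
SYN0034	2352	orf	stop_UAA	0	297		0	annotation_only,below_threshold,zero_window
SYN0035	3757	orf	stop_UAA	0	297		0	annotation_only,below_threshold,zero_window
SYN0036	4889	leader	start_AUG	1	-50	14.963	460	.
SYN0036	4880	leader	stop_UAA	1	-41	13.4667	460	annotation_only
SYN0036	4542	orf	stop_UAA	0	297		0	annotation_only,below_threshold,zero_window
SYN0037	5857	orf	stop_UAA	0	297		0	annotation_only,below_threshold,zero_window
SYN0038	7297	orf	start_AUG	2	152	40.4	2740	.
SYN0038	7152	orf	stop_UAA	0	297		0	annotation_only,below_threshold,zero_window
SYN0039	8321	orf	start_AUG	1	151	40.4	2740	.
SYN0039	8467	orf	stop_UAA	0	297		0	annotation_only,below_threshold,zero_window
SYN0040	9397	orf	start_AUG	2	152	40.4	2740	.
SYN0040	9252	orf	stop_UAA	0	297		0	annotation_only,below_threshold,zero_window
SYN0042	11901	leader	start_AUG	0	-252	20.2	460	.
SYN0042	11892	leader	stop_UAA	0	-243	20.2	460	annotation_only
SYN0042	11352	orf	stop_UAA	0	297		0	annotation_only,below_threshold,zero_window
SYN0043	12521	orf	start_AUG	1	151	40.4	2740	.
SYN0043	12667	orf	stop_UAA	0	297		0	annotation_only,below_threshold,zero_window
SYN0045	14767	orf	stop_UAA	0	297		0	annotation_only,below_threshold,zero_window
SYN0048	18162	orf	stop_UAA	0	297		0	annotation_only,below_threshold,zero_window
SYN0049	18930	leader	start_AUG	2	-250	20.2	460	.
SYN0049	18939	leader	stop_UAA	2	-241	20.2	460	annotation_only
SYN0049	19477	orf	stop_UAA	0	297		0	annotation_only,below_threshold,zero_window
SYN0050	20608	leader	start_AUG	2	-49	13.931	460	.
SYN0050	20599	leader	stop_UAA	2	-40	13.4667	460	annotation_only
SYN0050	20262	orf	stop_UAA	0	297		0	annotation_only,below_threshold,zero_window
SYN0051	21431	orf	start_AUG	1	151	40.4	2740	.
SYN0051	21577	orf	stop_UAA	0	297		0	annotation_only,below_threshold,zero_window
SYN0053	23677	orf	stop_UAA	0	297		0	annotation_only,below_threshold,zero_window
SYN0054	25011	leader	start_AUG	0	-252	20.2	460	.
SYN0054	25002	leader	stop_UAA	0	-243	20.2	460	annotation_only
SYN0054	24462	orf	stop_UAA	0	297		0	annotation_only,below_threshold,zero_window
SYN0055	25230	leader	start_AUG	2	-250	20.2	460	.
SYN0055	25239	leader	stop_UAA	2	-241	20.2	460	annotation_only
SYN0055	25777	orf	stop_UAA	0	297		0	annotation_only,below_threshold,zero_window
SYN0056	26707	orf	start_AUG	2	152	40.4	2740	.
SYN0056	26562	orf	stop_UAA	0	297		0	annotation_only,below_threshold,zero_window
SYN0058	29209	leader	start_AUG	2	-250	20.2	460	.
SYN0058	29200	leader	stop_UAA	2	-241	20.2	460	annotation_only
SYN0058	28662	orf	stop_UAA	0	297		0	annotation_only,below_threshold,zero_window
SYN0059	29977	orf	stop_UAA	0	297		0	annotation_only,below_threshold,zero_window
SYN0060	31109	leader	start_AUG	1	-50	14.963	460	.
SYN0060	31100	leader	stop_UAA	1	-41	13.4667	460	annotation_only
SYN0060	30762	orf	stop_UAA	0	297		0	annotation_only,below_threshold,zero_window
SYN0061	32077	orf	stop_UAA	0	297		0	annotation_only,below_threshold,zero_window
SYN0062	33517	orf	start_AUG	2	152	40.4	2740	.
SYN0062	33372	orf	stop_UAA	0	297		0	annotation_only,below_threshold,zero_window
SYN0064	35617	orf	start_AUG	2	152	40.4	2740	.
SYN0064	35472	orf	stop_UAA	0	297		0	annotation_only,below_threshold,zero_window
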