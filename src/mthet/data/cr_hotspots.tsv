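locus	position	major	minor	substitution_rate	n_persons	total_phps	median_maf_pct	min_maf_pct	max_maf_pct
MT-HV2	189	A	G	31	6	7	0.5	0.3	0.6
MT-HV1	16129	G	A	86	6	6	0.2	0.2	0.6
MT-HV2	152	T	C	157	5	7	0.2	0.2	5.1
MT-HV1	16293	A	G	17	5	5	0.3	0.2	0.5
Control region	16519	C	T	209	4	6	0.3	0.1	2.8
MT-HV2	146	T	C	109	4	4	0.3	0.1	0.4
MT-HV1	16093	C	T	79	3	6	3.0	1.6	12
MT-HV2	204	T	C	43	3	5	0.4	0.3	2.1
MT-HV1	16286	T	C	5	2	4	1.9	0.9	39.6
MT-HV1	16311	T	C	120	2	3	0.5	0.3	6.8
MT-HV2	214	A	G	10	2	3	2.3	0.2	49.6
Control region	16390	G	A	31	2	3	2.4	0.1	18.3
MT-HV2	195	T	C	98	2	2	2.6	0.4	4.7
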