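age	individual	position	substitution_rate	locus_printed	locus	mutation	major	minor	maf_buccal_pct	maf_blood_pct	polyphen
48	MW-0080	3586	.	MT-ND1	MT-ND1	NS	C	T	3.6	0	BENIGN
42	MW-0020	7348	.	MT-CO1	MT-CO1	NS	T	C	0.6	0.8	BENIGN
38	MW-0067	8034	.	MT-CO2	MT-CO2	NS	T	C	0.5	0.8	BENIGN
42	MW-0020	9325	2	MT-CO3	MT-CO3	NS	T	C	6.3	3.6	BENIGN
37	MW-0073	15731	3	MT-CYB	MT-CYB	NS	G	A	0.2	0	BENIGN
38	MW-0026	9164	.	MT-ATP8	MT-ATP6	NS	T	C	0	0.3	PROBABLY DAMAGING
42	MW-0020	9622	.	MT-CO3	MT-CO3	NS	C	T	0	0.1	PROBABLY DAMAGING
41	MW-0065	9774	.	MT-CO3	MT-CO3	NS	G	A	0.3	0	PROBABLY DAMAGING
37	MW-0012	9987	.	MT-CO3	MT-CO3	NS	T	C	0	0.8	PROBABLY DAMAGING
41	MW-0065	11634	.	MT-ND4	MT-ND4	NS	G	A	0	0.4	PROBABLY DAMAGING
41	MW-0065	14898	.	MT-CYB	MT-CYB	NS	T	C	0.4	0	PROBABLY DAMAGING
41	MW-0065	6179	3	MT-CO1	MT-CO1	S	G	A	1.0	3.9	.
58	MW-0087	8955	1	MT-ATP7	MT-ATP6	S	T	C	3.2	2.0	.
38	MW-0026	9740	1	MT-CO3	MT-CO3	S	C	T	20.7	17.5	.
38	MW-0026	11887	3	MT-ND4	MT-ND4	S	G	A	0	0.3	.
38	MW-0067	14020	4	MT-ND5	MT-ND5	S	T	C	0.4	0	.
38	MW-0026	14539	.	MT-ND6	MT-ND6	S	A	G	27.7	25.5	.
38	MW-0026	14560	12	MT-ND6	MT-ND6	S	G	A	0	0.4	.
37	MW-0073	15343	.	MT-CYB	MT-CYB	S	C	T	0.1	0	.
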