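name	start0	end0	strand	feature
CR-5prime	16023	16569	.	control_region
CR-3prime	0	576	.	control_region
HVS-I	16023	16365	.	hvs
HVS-II	56	372	.	hvs
MT-TF	576	647	H	tRNA
MT-RNR1	647	1601	H	rRNA
MT-TV	1601	1670	H	tRNA
MT-RNR2	1670	3229	H	rRNA
MT-TL1	3229	3304	H	tRNA
MT-ND1	3306	4262	H	protein_coding
MT-TI	4262	4331	H	tRNA
MT-TQ	4328	4400	L	tRNA
MT-TM	4401	4469	H	tRNA
MT-ND2	4469	5511	H	protein_coding
MT-TW	5511	5579	H	tRNA
MT-TA	5586	5655	L	tRNA
MT-TN	5656	5729	L	tRNA
MT-TC	5760	5826	L	tRNA
MT-TY	5825	5891	L	tRNA
MT-CO1	5903	7445	H	protein_coding
MT-TS1	7445	7514	L	tRNA
MT-TD	7517	7585	H	tRNA
MT-CO2	7585	8269	H	protein_coding
MT-TK	8294	8364	H	tRNA
MT-ATP8	8365	8572	H	protein_coding
MT-ATP6	8526	9207	H	protein_coding
MT-CO3	9206	9990	H	protein_coding
MT-TG	9990	10058	H	tRNA
MT-ND3	10058	10404	H	protein_coding
MT-TR	10404	10469	H	tRNA
MT-ND4L	10469	10766	H	protein_coding
MT-ND4	10759	12137	H	protein_coding
MT-TH	12137	12206	H	tRNA
MT-TS2	12206	12265	H	tRNA
MT-TL2	12265	12336	H	tRNA
MT-ND5	12336	14148	H	protein_coding
MT-ND6	14148	14673	L	protein_coding
MT-TE	14673	14742	L	tRNA
MT-CYB	14746	15887	H	protein_coding
MT-TT	15887	15953	H	tRNA
MT-TP	15955	16023	L	tRNA
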