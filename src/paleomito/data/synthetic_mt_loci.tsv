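16024	576	D-loop	D-loop/intergenic
577	647	TRNF	tRNA
648	1601	RNR1	rRNA
1602	1670	TRNV	tRNA
1671	3229	RNR2	rRNA
3230	3304	TRNL1	tRNA
3305	4262	ND1	protein_coding
4263	4469	TRN-cluster-1	tRNA
4470	5511	ND2	protein_coding
5512	5903	TRN-cluster-2	tRNA
5904	7445	CO1	protein_coding
7446	7585	TRN-cluster-3	tRNA
7586	8269	CO2	protein_coding
8270	8364	intergenic-1	D-loop/intergenic
8365	8526	ATP8	protein_coding
8527	9207	ATP6	protein_coding
9208	9990	CO3	protein_coding
9991	10058	TRNG	tRNA
10059	10404	ND3	protein_coding
10405	10469	TRNR	tRNA
10470	12137	ND4	protein_coding
12138	12336	TRN-cluster-4	tRNA
12337	14148	ND5	protein_coding
14149	14673	ND6	protein_coding
14674	14742	TRNE	tRNA
14747	15887	CYB	protein_coding
14743	14746	intergenic-2	D-loop/intergenic
15888	16023	TRN-cluster-5	tRNA
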