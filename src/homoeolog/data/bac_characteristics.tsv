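region	bac	marker_gene	sub_genome	homoeologous_group	assembly_phase	length_kb	overlap_kb	gene_incidence_bp	gene_space_pct
A	wc38j22	TrZPT2	O	3	2	61	51	6100	45.20
A	wc11l07	TrZPT2	P'	3	3	127		11545	23.05
B	wc113f04	TrDREB3	O	4	2	73	51	12166	28.34
B	wc88n22	TrDREB3	P'	4	3	101		10100	28.05
C	wc99k01	TrDHNb	O	3	3	152	50	8941	29.80
C	wc32k23	TrDHNb	P'	3	2	50		10000	23.47
D	wc88b23	TrANR	O	4	1	25	21	8333	36.77
D	wc36e03	TrANR	P'	4	1	24		6000	24.55
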