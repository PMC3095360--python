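gene	putative_function	exon_identity_pct	intron_identity_pct	protein_identity_pct	protein_similarity_pct	ks	ka	complete
A.5	Predicted protein 2	99.1	99.8	98.8	99	0.0019	0.0026	1
A.6	Predicted protein 3	99.1	100	98.3	99	0.0165	0.0074	1
A.7	Galactose oxidase	99.9	98.6	99.7	99.7	0	0.0011	1
A.10	Adenine phosphoribosyltransferase	100	99.8	100	100	0	0	1
A.11	ZPT2	97.1		97.9	98.4	0.0409	0.0022	1
B.5	Bristled 1	85.9	88.4	86.3	87.5	0.0797	0.0059	1
B.6	Ethylene insensitive 3	94.2						0
B.7	bZIP transcription factor	97.1	62.6	97.1	98.2	0.0715	0.0125	1
B.8	Acyl-CoA oxidase 2	98.4	86.8	99	99.6	0.0552	0.0046	1
B.9	Predicted protein 9	95.8	75.1	94.9	95.6	0.1019	0.0175	1
B.10	DREB3	96.8		97	98.4	0.1179	0.0127	1
C.7	SH3 domain-containing protein 2 (SH3P2)	98.7	82.6	98.9	99.4	0.0368	0.0051	1
C.8	MKRP2	98.5	92.2	99.3	99.7	0.0465	0.0062	1
C.9	Salt tolerance homolog 2	95.2	94.7	95.1	95.8	0.0586	0.0062	1
C.10	DHNb	96.8	85.2	97.2	98.2	0.1050	0.0099	1
C.11	Transcription factor/zinc-mediated transcriptional activator (SHL1)	90.7						0
D.2	Anthocyanidin reductase	97.8	83.7	98.8	99.1	0.0706	0.0039	1
D.3	Serine/threonine kinase	98.2	91.7	96.8	97.9	0.0252	0.0162	1
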