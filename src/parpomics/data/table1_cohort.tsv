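sample_id	germline_gene	er_status	tp53	rcb	tnbc_subtype	mutations_per_mb	purity	ploidy	analyzed
P15	BRCA1	TNBC	G266E	RCB-III	IM	0.67	0.23	1.5	1
P16	BRCA1	ER 5% weak, PR-	E258G	RCB-I		1.17	0.50	1.8	1
P17	BRCA1	TNBC	C141Y	pCR	IM	0.73	0.48	1.8	1
P18	BRCA1	TNBC	R175H	RCB-III	BL2	2.44	0.48	3.1	1
P21	BRCA2	TNBC	17:7,579,310	pCR	M	5.22	0.81	3.4	1
P23	BRCA1	TNBC	R175H	RCB-II	BL2	3.71	0.34	1.8	1
P24	BRCA1	TNBC	L265P	pCR	BL1	3.74	0.50	3.1	1
P25	BRCA1	ER+, PR+, HER2-	wt	RCB-II		2.54	0.63	2.0	1
P26	BRCA1	TNBC	Y220C	pCR	MSL	4.11	0.43	1.8	1
P30	BRCA2	ER+, PR+, HER2-	wt	pCR		2.14	0.23	2.0	1
P31	BRCA1	TNBC	R175H	RCB-II	BL1	3.66	0.40	2.2	1
P34	BRCA1	TNBC	V216M	RCB-II	BL1	1.71	0.21	1.7	1
P36	BRCA2	ER+, PR+, HER2-	wt	RCB-I		2.39	0.27	2.3	1
P19	BRCA1	TNBC	wt	pCR		1.09	0.0	2.0	0
P27	BRCA1	TNBC	wt	RCB-II		0.78	0.0	2.0	0
P29	BRCA1	TNBC	wt	pCR		0.97	0.0	2.0	0
P32	BRCA2	TNBC	wt	pCR		0.98	0.0	2.0	0
P35	BRCA1	ER+, PR-, HER2-	wt	pCR		0.68	0.0	2.0	0
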