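probe_id	gene_symbols	chromosome	coordinate	rho	p_value
cg02358190	MAST4	5	66187002	-0.92514	3.91E-08
cg04033580	C22orf45; UPB1	22	24891666	-0.8539	6.53E-06
cg13459303	TMEM176B; TMEM176A	7	150000000	-0.82912	2.11E-05
cg24644201	CREB3L1	11	46299066	0.822922	2.74E-05
cg25626312	CREB3L1	11	46299204	0.81776	3.39E-05
cg03885527	PLIN2	9	19125654	-0.81363	4.00E-05
cg05690644	GDF6	8	97158015	-0.81053	4.52E-05
cg23393637		14	95513095	-0.81053	4.52E-05
cg26981651	RNF5; RNF5P1	6	32147670	-0.81053	4.52E-05
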