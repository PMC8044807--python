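variant_id	major_allele	minor_allele	gene	weight	p_linear	risk_allele	chrom	pos	maf
rs62069959	G	A	PRKCA	2.299	0.001	G	17	64318923	0.196
rs7125415	G	A	DRD2	1.657	0.034	A	11	113000000	0.126
rs61131185	A	G	ATXN1	1.524	0.011	G	6	16623387	0.322
rs12665284	G	A	ATXN1	1.481	0.041	G	6	16626066	0.146
rs202146909	A	G	KCNJ3	1.414	0.042	A	2	156000000	0.193
rs493352	G	A	ATXN1	1.242	0.031	G	6	16744169	0.488
rs9754467	A	G	CACNG2	1.166	0.032	A	22	37019059	0.222
rs12198202	A	G	ATXN1	1.064	0.005	A	6	16679771	0.424
rs11079653	T	A	PRKCA	0.98	0.011	T	17	64352329	0.202
rs2850125	G	A	KCNJ6	0.936	0.046	G	21	39130114	0.456
rs9914723	G	A	PRKCA	0.917	0.004	A	17	64716397	0.196
rs7220480	A	G	PRKCA	0.857	0.048	G	17	64686679	0.406
rs2891519	G	A	KCNK3	0.835	0.008	A	2	26954991	0.220
rs200369418	A	C	PRKCA	0.816	0.028	A	17	64762496	0.500
rs3812204	G	A	ATXN1	0.789	0.038	A	6	16698022	0.345
rs4716060	C	A	ATXN1	0.772	0.038	A	6	16310456	0.345
rs6459476	A	C	ATXN1	0.736	0.048	C	6	16618187	0.348
rs227912	A	G	PRKCA	0.678	0.049	A	17	64610729	0.246
rs744214	G	A	PRKCA	0.634	0.017	G	17	64334856	0.316
rs1992701	G	A	KCNJ3	0.584	0.047	A	2	156000000	0.453
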