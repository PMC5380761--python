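pair_id	sg	n_sequences	branch	structural_sg	known_genes	np0	lnl0	np1	lnl1	printed_p	printed_code	n_sites	ecd_sites	icd_sites
1	SG_II	101	SG_II-3	B.1	DOCS1	203	-47756.49038	204	-47755.94453	0.2960935	ns
1	SG_II	101	SG_II-4	B.2	NIK3	203	-47761.1425	204	-47755.93314	0.0012474	*	3	3
2	SG_III	92	SG_III-3	C2		185	-87752.00789	186	-87746.86878	0.0013461	*	1	1
2	SG_III	92	SG_III-4	C2		185	-87749.51178	186	-87741.65272	0.0000735	**	0
3	SG_III	126	SG_III-9	C6.1	DIPM1, DIPM3	253	-58707.08864	254	-58683.61908	0.000000	**	11	4	7
3	SG_III	126	SG_III-8	C6.2		253	-58712.53117	254	-58695.21242	0.000000	**	5	1	4
4	SG_Xa	145	SG_Xa-1	L	BIR1	291	-80168.41936	292	-80165.39924	0.013983288	ns
4	SG_Xa	145	SG_Xa-2	L	BIR2, BIR3, BIR4	291	-80166.7335	292	-80164.42719	0.031737545	ns
5	SG_Xb	162	SG_Xb-5	M1.1	PSKR2	325	-148131.1793	326	-148124.8687	0.000381394	**	1	1
5	SG_Xb	162	SG_Xb-6	M1.1	PSKR1	325	-148131.1246	326	-148120.4449	0.000004	**	1	1
6	SG_XI	99	SG_XI-20	N3.2	PXC3	199	-40840.3843	200	-40833.87176	0.00030735	**	0
6	SG_XI	99	SG_XI-19	N3.2		199	-40838.95437	200	-40833.37719	0.000838	*	1	1
7	SG_XI	116	SG_XI-9	N4	PEPR1, PEPR2	233	-80676.72267	234	-80660.28275	9.80354E-09	**	12	8	4
7	SG_XI	116	SG_XI-8	N4		233	-80679.22227	234	-80660.42399	0.000000	**	9	3	6
8	SG_XI	115	SG_XI-14	N6.2	SKM2	231	-126354.8399	232	-126314.768	3.48134E-19	**	20	12	6
8	SG_XI	115	SG_XI-15	N6.1		231	-126374.0677	232	-126335.0153	0.000000	**	12	8	3
9	SG_XI	132	SG_XI-18	N6.1	PXY	265	-131270.9444	266	-131195.5224	1.13374E-34	**	5	4	1
9	SG_XI	132	SG_XI-17	N6.2	PXL1, PXL2	265	-131261.1148	266	-131172.9143	2.96009E-40	**	23	14	9
10	SG_XIIa	101	SG_XIIa-2	O		203	-69490.32865	204	-69487.62542	0.020062	ns
10	SG_XIIa	101	SG_XIIa-3	O		203	-69490.53986	204	-69488.57373	0.047369	ns
11	SG_XIIIa	143	SG_XIIIa-2	Q		287	-66690.11714	288	-66686.45331	0.006790	ns
11	SG_XIIIa	143	SG_XIIIa-1	Q	FEI1, FEI2	287	-66684.64365	288	-66678.94678	0.000737	*	0
12	SG_XIIIb	143	SG_XIIIb-1	R.2	ERL1, ERL2	161	-79161.61197	162	-79144.08871	3.21923E-09	**	26	14	8
12	SG_XIIIb	143	SG_XIIIb-2	R.1	ER	161	-79156.50926	162	-79146.91448	0.000012	**	11	8	3
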