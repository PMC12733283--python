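family_id	proband_id	variant_id	gene	sex	cleft_type	cleft_side	family_history	hgvs_c	hgvs_p	rsid	maf_nfe	gt_proband	gt_father	gt_mother	father_affected	mother_affected	parentage_verified	ofc_syndromic	ofc_nonsyndromic	ofc_ko_mouse	clinvar_lp_for_trait	inheritance_group
FAM_1	CLP_1	FOXA2:c.779G>C	FOXA2	M	CLP	right	NO	c.779G>C	p.Arg260Pro	novel		het	wt	wt	false	false	true	false	false	false	false	de_novo
FAM_2	CLP_2	MAML1:c.193C>T	MAML1	M	CLP	right	NO	c.193C>T	p.Gln65Ter	novel		het	wt	wt	false	false	true	false	false	false	false	de_novo
FAM_3	CLP_3	ZNF319:c.190C>T	ZNF319	M	CLP	bilateral	NO	c.190C>T	p.Gln64Ter	novel		het	wt	wt	false	false	true	false	false	false	false	de_novo
FAM_4	CLP_4	GDF7:c.1081C>T	GDF7	M	CLP	bilateral	YES—father	c.1081C>T	p.Leu361Phe	novel		het	het	wt	true	false	true	false	false	false	false	affected_parent
FAM_5	CLP_5	FAT1:c.2681dupA	FAT1	M	CLP	right	YES—mother	c.2681dupA	p.Ile895AspfsTer2	novel		het	wt	het	false	true	true	false	false	false	false	affected_parent
FAM_6	CLP_6	VWA8:c.2003G>A	VWA8	M	CLP	bilateral	YES—father	c.2003G>A	p.Arg668Gln	rs138075452	4.72e-3	het	het	wt	true	false	true	false	true	false	true	affected_parent
FAM_7	CLP_7	CTNNA1:c.2429C>T	CTNNA1	F	CLP	bilateral	YES—ex. paternal fam.	c.2429C>T	p.Ser810Phe	novel		het	het	wt	false	false	true	false	true	false	false	healthy_parent
FAM_8	CLP_8	EFNB2:c.590G>T	EFNB2	M	CLP	left	YES—ex. maternal fam.	c.590G>T	p.Ser197Ile	rs250151379		het	wt	het	false	false	true	false	true	true	false	healthy_parent
FAM_9	CLP_9	HIF1A:c.806G>A	HIF1A	F	CLP	left	YES—ex. maternal fam.	c.806G>A	p.Arg269Gln	rs2044522437	6.78e-6	het	wt	het	false	false	true	false	true	false	false	healthy_parent
FAM_10	CLP_10	LAMA5:c.3520_3521delAG	LAMA5	M	CLP	bilateral	YES—ex. family	c.3520_3521delAG	p.Arg1174AlafsTer19	novel		het	het	wt	false	false	true	false	true	false	false	healthy_parent
FAM_11	CLP_11	LRP5:c.3638-1G>A	LRP5	M	CLP	left	YES—sister	c.3638-1G>A		novel		het	wt	het	false	false	true	false	false	false	false	healthy_parent
FAM_11	CLP_12	LRP5:c.3638-1G>A	LRP5	F	CLP	left	YES—brother	c.3638-1G>A		novel		het	wt	het	false	false	true	false	false	false	false	healthy_parent
FAM_13	CLP_13	AGO1:c.1823C>T	AGO1	F	CL	right	NO	c.1823C>T	p.Ser608Phe	rs1353927503	8.48e-7	het	wt	het	false	false	true	false	false	false	false	healthy_parent
FAM_14	CLP_14	ARID1A:c.6428G>A	ARID1A	M	CLP	left	NO	c.6428G>A	p.Arg2143His	rs2124148967	1.70e-6	het	wt	het	false	false	true	false	false	false	false	healthy_parent
FAM_15	CLP_15	ATN1:c.2239C>A	ATN1	M	CL	right	NO	c.2239C>A	p.Pro747Thr	rs782670138	7.85e-6	het	het	wt	false	false	true	true	false	false	false	healthy_parent
FAM_16	CLP_16	ATP1A1:c.1934C>T	ATP1A1	M	CLP	left	NO	c.1934C>T	p.Ala645Val	rs2101057973		het	het	wt	false	false	true	false	false	false	false	healthy_parent
FAM_17	CLP_17	EXT1:c.493C>G	EXT1	M	CLP	bilateral	NO	c.493C>G	p.Gln165Glu	rs2130043213		het	wt	het	false	false	true	false	false	true	false	healthy_parent
FAM_18	CLP_18	HAND1:c.328A>C	HAND1	M	CLP	left	NO	c.328A>C	p.Ile110Leu	rs905545828	1.70e-6	het	het	wt	false	false	true	false	false	true	false	healthy_parent
FAM_19	CLP_19	HOXB3:c.374T>G	HOXB3	F	CLP	bilateral	NO	c.374T>G	p.Leu125Arg	rs2068774883		het	wt	het	false	false	true	false	false	false	false	healthy_parent
FAM_20	CLP_20	IFT172:c.4096G>T	IFT172	F	CLP	right	NO	c.4096G>T	p.Asp1366Tyr	rs776240963	5.09e-6	het	wt	het	false	false	true	true	true	true	false	healthy_parent
FAM_21	CLP_21	KRT17:c.695A>G	KRT17	M	CL	right	NO	c.695A>G	p.Gln232Arg	rs1484519975	1.7e-6	het	wt	het	false	false	true	false	false	true	false	healthy_parent
FAM_22	CLP_22	MEN1:c.1565G>T	MEN1	M	CLP	bilateral	NO	c.1565G>T	p.Arg522Leu	novel		het	wt	het	false	false	true	false	false	true	false	healthy_parent
FAM_23	CLP_23	MYH3:c.52C>T	MYH3	F	CL	right	NO	c.52C>T	p.Arg18Trp	rs750940457	5.93e-6	het	wt	het	false	false	true	true	true	false	false	healthy_parent
FAM_24	CLP_24	NCOR2:c.650C>T	NCOR2	M	CLP	bilateral	NO	c.650C>T	p.Pro217Leu	rs199588853	2.72e-5	het	wt	het	false	false	true	false	false	true	false	healthy_parent
FAM_25	CLP_25	NXN:c.503A>C	NXN	F	CLP	left	NO	c.503A>C	p.Lys168Thr	novel		het	wt	het	false	false	true	true	false	true	false	healthy_parent
FAM_26	CLP_26	ROBO1:c.2026C>T	ROBO1	F	CLP	right	NO	c.2026C>T	p.Arg676Trp	novel		het	het	wt	false	false	true	false	false	true	false	healthy_parent
FAM_27	CLP_27	RPGRIP1L:c.413A>G	RPGRIP1L	F	CLP	bilateral	NO	c.413A>G	p.Gln138Arg	rs2544706158		het	wt	het	false	false	true	true	false	true	false	healthy_parent
FAM_28	CLP_28	RYR1:c.9136C>G	RYR1	M	CLP		NO	c.9136C>G	p.Leu3046Val	rs2145659189	0.00	het	het	wt	false	false	true	true	true	true	false	healthy_parent
FAM_28	CLP_28	RYR1:c.9198C>G	RYR1	M	CLP		NO	c.9198C>G	p.Asn3066Lys	rs201863144	0.00	het	het	wt	false	false	true	false	false	false	false	healthy_parent
FAM_29	CLP_29	SLC32A1:c.466G>T	SLC32A1	F	CLP	bilateral	NO	c.466G>T	p.Ala156Ser	rs2515237904		het	het	wt	false	false	true	false	false	true	false	healthy_parent
FAM_30	CLP_30	TENM4:c.7916G>A	TENM4	F	CLP	right	NO	c.7916G>A	p.Arg2639Gln	rs775067963	2.20e-5	het	het	wt	false	false	true	false	true	false	false	healthy_parent
FAM_31	CLP_31	TP53BP2:c.1757C>A	TP53BP2	F	CLP	left	NO	c.1757C>A	p.Ala586Asp	rs2464444021		het	wt	het	false	false	true	false	false	true	false	healthy_parent
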