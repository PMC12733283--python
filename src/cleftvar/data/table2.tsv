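variant_id	gene	consequence	hgvs_c	hgvs_p	acmg	pli	domino_class	domino_ad_prob	SIFT	SIFT4G	PolyPhen2_HDIV	PolyPhen2_HVAR	MutationTaster	MutationAssessor	PROVEAN	M-CAP	MutPred2	PrimateAI	DEOGEN2	ClinPred	LIST-S2	ESM1b	AlphaMissense	fathmm-XF	MetaSVM	MetaLR	MetaRNN	REVEL	BayesDel_addAF	BayesDel_noAF	ada	cadd	dann	mutpred_lof
AGO1:c.1823C>T	AGO1	missense	c.1823C>T	p.Ser608Phe	VUS	1.00	very_likely_dominant	0.999	D	D	D	D	D	H	D	D	PS	D	D	D	D	D	P	D	D	T	D	0.9	D	D		29.20	1.00	
ARID1A:c.6428G>A	ARID1A	missense	c.6428G>A	p.Arg2143His	VUS	1.00	very_likely_dominant	1.000	D	D	D	D	D	M	D	D	UC	D	T	D	D	D	P	D	T	T	D	0.91	D	D		32.00	1.00	
ATN1:c.2239C>A	ATN1	missense	c.2239C>A	p.Pro747Thr	VUS	1.00	very_likely_dominant	0.943	D	D	D	D	D	M	D	D	BP	T	D	D	D	D	P	D	D	D	D	0.8	D	D		26.30	1.00	
ATP1A1:c.1934C>T	ATP1A1	missense	c.1934C>T	p.Ala645Val	VUS	1.00	very_likely_dominant	0.999	D	D	D	D	D	L	D	D	PS	D	D	D	D	D	P	D	D	D	D	0.95	D	D		27.00	1.00	
CTNNA1:c.2429C>T	CTNNA1	missense	c.2429C>T	p.Ser810Phe	VUS	0.97	very_likely_dominant	1.000	D	D	D	D	N	M	D	D	PP	D	D	D	D	D	P	D	T	T	D	0.83	D	D		33.00	1.00	
EFNB2:c.590G>T	EFNB2	missense	c.590G>T	p.Ser197Ile	VUS	1.00	very_likely_dominant	0.998			B	B		L		D	PP	T	T	D	D	T	B	D	T	D	D		D	D		25.40	0.99	
EXT1:c.493C>G	EXT1	missense	c.493C>G	p.Gln165Glu	VUS	1.00	very_likely_dominant	0.991	T	T	P	B	D	L	N	D	UC	T	D	D	D	D	B	D	D	D	D	0.81	D	D		24.70	0.58	
FAT1:c.2681dupA	FAT1	frameshift	c.2681dupA	p.Ile895AspfsTer2	VUS	0.00	very_likely_recessive	0.178																										0.54
FOXA2:c.779G>C	FOXA2	missense	c.779G>C	p.Arg260Pro	VUS	0.97	likely_dominant	0.792		D			D			D	PS	D		D	D	D	LP	D	D	D	D	0.99	D	D		35.00	1.00	
GDF7:c.1081C>T	GDF7	missense	c.1081C>T	p.Leu361Phe	VUS	0.00	very_likely_dominant	0.991	D	D	D	D	N	M	D	D	UC	D	D	D	D	D	P	N	D	D	D	0.86	D	T		27.00	1.00	
HAND1:c.328A>C	HAND1	missense	c.328A>C	p.Ile110Leu	VUS	0.01	very_likely_dominant	0.839	T	T	D	D	N	N	N	D	UC	D	D	D	D	D	P	D	D	D	D	0.9	D	D		25.90	0.99	
HIF1A:c.806G>A	HIF1A	missense	c.806G>A	p.Arg269Gln	VUS	1.00	very_likely_dominant	1.000	D	D	D	D	D	M	D	D	PM	D	D	D	D	D	P	D	T	T	D	0.85	D	D		28.40	1.00	
HOXB3:c.374T>G	HOXB3	missense	c.374T>G	p.Leu125Arg	VUS	0.00	very_likely_dominant	0.988	T	T	D	D		M	D	D	UC	T	D	D		D	A		D	D	D	0.87	D	D		26.40	0.99	
IFT172:c.4096G>T	IFT172	missense	c.4096G>T	p.Asp1366Tyr	VUS	0.00	very_likely_recessive	0.152	D	D	D	D	D	M	D	D	PP	T	D	D	D	D	A	D	D	D	D	0.93	D	D		26.30	1.00	
KRT17:c.695A>G	KRT17	missense	c.695A>G	p.Gln232Arg	VUS	0.00	very_likely_recessive	0.152	D	D	B	B	D	M	D	D	UC	T	D	D	T	D	B	D	D	D	D	0.85	D	T		25.10	1.00	
LAMA5:c.3520_3521delAG	LAMA5	frameshift	c.3520_3521delAG	p.Arg1174AlafsTer19	VUS	0.00	likely_recessive	0.201																										0.55
LRP5:c.3638-1G>A	LRP5	splicing	c.3638-1G>A		VUS	0.94	very_likely_dominant	0.946																							0.999		0.99	
MAML1:c.193C>T	MAML1	stop_gain	c.193C>T	p.Gln65Ter	LP	1.00	very_likely_dominant	0.998					A									D		N					D	D		37.00	1.00	0.50
MEN1:c.1565G>T	MEN1	missense	c.1565G>T	p.Arg522Leu	VUS	1.00	very_likely_dominant	1.000								D	UC	D		D		T		D	D	D		0.93	D	D		23.40	1.00	
MYH3:c.52C>T	MYH3	missense	c.52C>T	p.Arg18Trp	VUS	0.00	likely_recessive	0.400		D	D	D		H		D	PS	D	D	D	D	D	P	D	D	D	D		D	D		32.00	1.00	
NCOR2:c.650C>T	NCOR2	missense	c.650C>T	p.Pro217Leu	VUS	1.00	very_likely_dominant	0.999	D	D			N	L	D	D	BP	T	D	D	D	D	A	D	T	T	D	0.74	T	T		25.80	0.98	
NXN:c.503A>C	NXN	missense	c.503A>C	p.Lys168Thr	VUS	0.37	dominant_or_recessive	0.510	T	T	D	D		L	D	D	PM	D	T	D	D	D	A	D	T	D	D	0.79	D	D		24.00	1.00	
ROBO1:c.2026C>T	ROBO1	missense	c.2026C>T	p.Arg676Trp	VUS	0.00	dominant_or_recessive	0.539	D	D	D	D	D	M	D	D	PM	T	T	D	D	D	P	D	T	T	D	0.81	D	D		27.60	1.00	
RPGRIP1L:c.413A>G	RPGRIP1L	missense	c.413A>G	p.Gln138Arg	VUS	0.00	very_likely_recessive	0.071			D	D		M		D	BM	T		D	D	T	B	D	D	D	D	0.67	D	D		23.60	1.00	
RYR1:c.9136C>G	RYR1	missense	c.9136C>G	p.Leu3046Val	VUS	0.00	very_likely_dominant	0.987	D		P	B	N	M	N	D	PP	T	D	D	D	D	A	D	D	T	D	0.74	T	T		22.20	0.99	
RYR1:c.9198C>G	RYR1	missense	c.9198C>G	p.Asn3066Lys	VUS	0.00	very_likely_dominant	0.987	T		B	B	D	L	D	D	UC	T	D	D	D	D	P	D	D	D	D	0.72	T	T		20.10	1.00	
SLC32A1:c.466G>T	SLC32A1	missense	c.466G>T	p.Ala156Ser	VUS	1.00	likely_dominant	0.737	D	D	D	D	D	M	D	T	PP	D	T	D	D	T	A	D	T	T	D	0.53	T	T		29.70	1.00	
TENM4:c.7916G>A	TENM4	missense	c.7916G>A	p.Arg2639Gln	VUS	1.00	very_likely_dominant	0.878	D	D	D	D	N	M	N	D	UC	T	T	D	D	T	B	D	D	D	D	0.79	T	T		28.60	1.00	
TP53BP2:c.1757C>A	TP53BP2	missense	c.1757C>A	p.Ala586Asp	VUS	0.00	dominant_or_recessive	0.438	D	D			N		D	D	UC	T		D	D	T	LP	D	T	T	D	0.52	D	D		24.00	1.00	
VWA8:c.2003G>A	VWA8	missense	c.2003G>A	p.Arg668Gln	VUS (leaning LP)	0.00	very_likely_recessive	0.092	D	D	D	D	A	M	D	D	UC	T	T	T	D	D	A	D	T	T	T	0.73	T	D		27.90	1.00	
ZNF319:c.190C>T	ZNF319	stop_gain	c.190C>T	p.Gln64Ter	LP	0.51	likely_dominant	0.744														D		N					D	D		38.00	0.99	0.45
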