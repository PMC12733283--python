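gene	n_snvs_plotted	rsid	chrom	pos	context	maf	p_trend	or_allelic
AGO1	11	rs6682769	chr1	35860595	22.6 kb upstream, intergenic	0.06	3.36e-2	1.57
ARID1A	20	rs4466675	chr1	26693521	2.5 kb upstream, intergenic	0.48	2.05e-2	0.79
ATN1	43	rs10744724	chr12	6956118	13.8 kb downstream, within PTPN6	0.06	6.70e-3	0.50
ATP1A1	29	rs766429	chr1	116495418	90.6 kb downstream, intergenic	0.21	1.76e-1	0.84
CTNNA1	33	rs12108892	chr5	138963941	28.9 kb downstream, within SIL1	0.39	8.13e-2	0.83
EFNB2	91	rs7490929	chr13	106431374	58.4 kb downstream, intergenic	0.07	3.75e-2	1.51
EXT1	128	rs7837891	chr8	117807339	exonic (synonymous variant)	0.44	9.56e-4	0.70
FAT1	93	rs28647489	chr4	186609868	exonic (missense variant)	0.14	3.18e-2	0.71
FOXA2	35	rs2404167	chr20	22528795	52.2 kb downstream, intergenic	0.10	3.77e-2	1.62
GDF7	64	rs340596	chr2	20689994	10.8 kb downstream, within C2orf43	0.43	7.43e-3	0.76
HAND1	86	rs283438	chr5	154494000	15.8 kb upstream, intergenic	0.17	3.06e-2	1.34
HIF1A	35	rs17099248	chr14	61832287	84.0 kb downstream, intergenic	0.12	2.57e-2	0.68
HOXB3	52	rs890435	chr17	48642037	51.8 kb upstream, intergenic	0.40	1.03e-2	1.31
IFT172	33	rs3811644	chr2	27579938	90.2 kb upstream, within SPATA31H1	0.21	2.49e-1	0.86
KRT17	31	rs7503702	chr17	41609234	10.2 kb upstream, intergenic	0.40	1.04e-2	1.30
LAMA5	72	rs4925238	chr20	62431508	64.2 kb upstream, intergenic	0.06	1.79e-2	1.61
LRP5	51	rs314779	chr11	68330358	intronic	0.23	2.76e-2	0.76
MAML1	41	rs28564876	chr5	179651067	81.8 kb upstream, intergenic	0.41	9.34e-4	1.43
MEN1	29	rs10897529	chr11	64829444	18.9 kb upstream, within CDC42BPG	0.35	2.31e-1	1.14
MYH3	30	rs6503319	chr17	10670842	13.5 kb upstream, intergenic	0.25	3.90e-2	1.27
NCOR2	154	rs7132377	chr12	124667448	99.8 kb upstream, intergenic	0.09	4.63e-3	0.56
NXN	127	rs8081951	chr17	933301	intronic	0.18	2.52e-4	1.62
ROBO1	176	rs1865862	chr3	78754700	intronic	0.28	1.25e-2	0.74
RPGRIP1L	58	rs1421085	chr16	53767042	63.2 kb upstream, within FTO	0.48	2.49e-3	1.36
RYR1	59	rs4802351	chr19	38358156	72.5 kb upstream, within CATSPERG	0.14	2.50e-2	0.70
SLC32A1	41	rs2902891	chr20	38681144	43.3 kb upstream, intergenic	0.30	7.65e-2	1.22
TENM4	312	rs12362098	chr11	78857065	intronic	0.16	2.07e-3	1.50
TP53BP2	51	rs7535882	chr1	223857777	11.8 kb upstream, intergenic	0.07	1.16e-3	1.80
VWA8	118	rs12585194	chr13	41977432	16.3 kb upstream, within VWA8−AS1	0.13	1.43e-2	1.46
ZNF319	48	rs17241022	chr16	57920621	74.1 kb downstream, within CNGB1	0.10	4.40e-2	0.68
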