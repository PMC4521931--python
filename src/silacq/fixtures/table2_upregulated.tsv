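accession	gene	protein_name	ml_average	hl_average	log2_ml	log2_hl	z_ml	z_hl
C9JGI3_HUMAN	TYMP	Thymidine phosphorylase	39.51	1.43	5.30	0.51	4.35	0.47
FOLR1_HUMAN	FOLR1	Folate receptor alpha	31.73	2.91	4.99	1.54	4.09	1.30
J3QRJ3_HUMAN	THY1	Thy-1 membrane glycoprotein	29.72	2.57	4.89	1.36	4.01	1.16
RCN3_HUMAN	RCN3	Reticulocalbin-3	23.97	3.29	4.58	1.72	3.76	1.45
STEA4_HUMAN	STEAP4	Metalloreductase STEAP4	23.43	4.23	4.55	2.08	3.74	1.74
EF1A2_HUMAN	EEF1A2	Elongation factor 1-alpha 2	17.58	0.87	4.14	-0.20	3.40	-0.10
1433S_HUMAN	SFN	14-3-3 protein sigma	16.87	3.27	4.08	1.71	3.35	1.44
DDX21_HUMAN	DDX21	Nucleolar RNA helicase 2	14.33	10.65	3.84	3.41	3.16	2.82
KCRB_HUMAN	CKB	Creatine kinase B-type	14.15	1.30	3.82	0.38	3.15	0.37
CPSM_HUMAN	CPS1	Carbamoyl-phosphate synthase [ammonia], mitochondrial	12.22	0.99	3.61	-0.01	2.98	0.05
MTAP_HUMAN	MTAP	S-methyl-5-thioadenosine phosphorylase	11.66	10.09	3.54	3.33	2.92	2.75
ASSY_HUMAN	ASS1	Argininosuccinate synthase	11.08	1.86	3.47	0.89	2.86	0.78
H0YDA6_HUMAN	NAPRT1	Nicotinate phosphoribosyltransferase	10.23	2.82	3.35	1.49	2.77	1.27
1A68_HUMAN	HLA-A	HLA class I histocompatibility antigen, A-32 alpha chain	8.34	0.44	3.06	-1.19	2.53	-0.91
EPIPL_HUMAN	EPPK1	Epiplakin	8.12	0.86	3.02	-0.21	2.50	-0.11
PGH2_HUMAN	PTGS2	Prostaglandin G/H synthase 2	7.95	1.13	2.99	0.17	2.48	0.20
HPDL_HUMAN	HPDL	4-hydroxyphenylpyruvate dioxygenase-like protein	7.93	1.13	2.99	0.18	2.47	0.20
K1C18_HUMAN	KRT18	Keratin, type I cytoskeletal 18	7.51	2.18	2.91	1.13	2.41	0.97
WDR3_HUMAN	WDR3	WD repeat-containing protein 3	7.26	3.36	2.86	1.75	2.37	1.47
PADI2_HUMAN	PADI2	Protein-Arg deiminase type-2	6.99	1.38	2.81	0.46	2.33	0.43
EXOS4_HUMAN	EXOSC4	Exosome complex component RRP41	6.57	3.20	2.72	1.68	2.26	1.42
A6PVX1_HUMAN	SELENBP1	Selenium-binding protein 1	6.41	1.04	2.68	0.06	2.23	0.10
KYNU_HUMAN	KYNU	Kynureninase	6.32	0.35	2.66	-1.50	2.21	-1.16
4F2_HUMAN	SLC3A2	4F2 cell-surface antigen heavy chain	6.24	0.88	2.64	-0.18	2.19	-0.09
PO210_HUMAN	NUP210	Nuclear pore membrane glycoprotein 210	6.16	1.05	2.62	0.07	2.18	0.12
G3V588_HUMAN	ITPK1	Inositol-tetrakisphosphate 1-kinase	6.09	1.71	2.61	0.77	2.17	0.68
ANM7_HUMAN	PRMT7	Protein Arg N-methyltransferase 7	5.99	2.18	2.58	1.13	2.15	0.97
S100P_HUMAN	S100P	Protein S100-P	5.92	0.62	2.57	-0.69	2.13	-0.50
B0S8I7_HUMAN	LAGE3	L antigen family member 3	5.87	4.50	2.55	2.17	2.12	1.81
J3QKT4_HUMAN	PYCR1	Pyrroline-5-carboxylate reductase;	5.72	2.35	2.52	1.23	2.09	1.05
MCMBP_HUMAN	MCMBP	Mini-chromosome maintenance complex-binding protein	5.65	4.77	2.50	2.25	2.08	1.88
PRI2_HUMAN	PRIM2	DNA primase large subunit	5.47	4.59	2.45	2.20	2.04	1.84
K1C17_HUMAN	KRT17	Keratin, type I cytoskeletal 17	5.39	0.89	2.43	-0.16	2.02	-0.07
LAT1_HUMAN	SLC7A5	Large neutral amino acids transporter small subunit 1	5.35	1.27	2.42	0.34	2.01	0.34
MYPN_HUMAN	MYPN	Myopalladin	5.34	0.88	2.42	-0.19	2.01	-0.09
NPM3_HUMAN	NPM3	Nucleoplasmin-3	5.29	3.29	2.40	1.72	2.00	1.45
UHRF1_HUMAN	UHRF1	E3 ubiquitin-protein ligase UHRF1	4.98	5.13	2.32	2.36	1.93	1.97
ITA6_HUMAN	ITGA6	Integrin alpha-6	4.58	12.65	2.19	3.66	1.83	3.02
CND3_HUMAN	NCAPG	Condensin complex subunit 3	4.04	5.67	2.01	2.50	1.69	2.08
UBS3B_HUMAN	UBASH3B	Ubiquitin-associated and SH3 domain-containing protein B	3.88	6.30	1.96	2.66	1.64	2.21
E9PD53_HUMAN	SMC4	Structural maintenance of chromosomes protein	3.51	5.72	1.81	2.52	1.52	2.09
KIF4A_HUMAN	KIF4A	Chromosome-associated kinesin KIF4A	3.26	6.56	1.70	2.71	1.44	2.25
MRP_HUMAN	MARCKSL1	MARCKS-related protein	2.74	5.39	1.45	2.43	1.23	2.02
CTRO_HUMAN	CIT	Citron Rho-interacting kinase	2.66	5.31	1.41	2.41	1.20	2.01
CIP2A_HUMAN	KIAA1524	Protein CIP2A	1.87	5.15	0.90	2.36	0.79	1.97
MAGA4_HUMAN	MAGEA4	Melanoma-associated antigen 4	1.48	17.47	0.56	4.13	0.51	3.40
PLEK2_HUMAN	PLEK2	Pleckstrin-2	0.98	5.95	-0.02	2.57	0.04	2.14
AL1A3_HUMAN	ALDH1A3	Aldehyde dehydrogenase family 1 member A3	0.93	13.75	-0.11	3.78	-0.03	3.12
RGS10_HUMAN	RGS10	Regulator of G-protein signaling 10	0.79	6.50	-0.34	2.70	-0.22	2.24
E41L3_HUMAN	EPB41L3	Band 4.1-like protein 3	0.72	6.54	-0.47	2.71	-0.33	2.25
UCHL1_HUMAN	UCHL1	Ubiquitin carboxyl-terminal hydrolase isozyme L1	0.42	9.45	-1.25	3.24	-0.95	2.68
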