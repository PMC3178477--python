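no	entry_name	accession	description	g	p	rsc	count_lcnec	count_sclc
1	AK1C3	P42330	Aldo-keto reductase family 1 member C3	39.1	3.93E-10	4.91	25	0
2	AK1C1	Q04828	Aldo-keto reductase family 1 member C1	37.4	9.56E-10	4.86	24	0
3	FABP7	O15540	Fatty acid-binding protein, brain	21.9	2.89E-06	4.22	15	0
4	ENOB	P13929	Beta-enolase	22.2	2.50E-06	3.61	18	1
5	AL1A1	P00352	Retinal dehydrogenase 1	11.8	6.07E-04	3.55	9	0
6	4F2	P08195	4F2 cell-surface antigen heavy chain	11.8	6.07E-04	3.55	9	0
7	1C12	P30508	HLA class I histocompatibility antigen, Cw-12 alpha chain precursor	11.8	6.07E-04	3.55	9	0
8	TBA4A	P68366	Tubulin alpha-4A chain	11.8	6.07E-04	3.55	9	0
9	LG3BP	Q08380	Galectin-3-binding protein precursor	20.6	5.77E-06	3.54	17	1
10	1C03	P04222	HLA class I histocompatibility antigen, Cw-3 alpha chain precursor	10.1	1.48E-03	3.40	8	0
11	TKT	P29401	Transketolase	8.46	3.62E-03	3.24	7	0
12	VTNC	P04004	Vitronectin precursor	6.85	8.87E-03	3.05	6	0
13	G6PD	P11413	Glucose-6-phosphate 1-dehydrogenase	6.85	8.87E-03	3.05	6	0
14	PRDX4	Q13162	Peroxiredoxin-4	6.85	8.87E-03	3.05	6	0
15	VDAC1	P21796	Voltage-dependent anion-selective channel protein 1	6.85	8.87E-03	3.05	6	0
16	1B15	P30464	HLA class I histocompatibility antigen, B-15 alpha chain precursor	6.85	8.87E-03	3.05	6	0
17	VILI	P09327	Villin-1	6.85	8.87E-03	3.05	6	0
18	DESP	P15924	Desmoplakin	11.19	8.24E-04	2.96	11	1
19	AHSA1	O95433	Activator of 90 kDa heat shock protein ATPase homolog 1	5.27	2.18E-02	2.84	5	0
20	COPB	P53618	Coatomer subunit beta	5.27	2.18E-02	2.84	5	0
21	TMEDA	P49755	Transmembrane emp24 domain-containing protein 10 precursor	5.27	2.18E-02	2.84	5	0
22	CD44	P16070	CD44 antigen precursor	5.27	2.18E-02	2.84	5	0
23	COPA	P53621	Coatomer subunit alpha	5.27	2.18E-02	2.84	5	0
24	TBB4Q	Q99867	Putative tubulin beta-4q chain	5.27	2.18E-02	2.84	5	0
25	THIL	P24752	Acetyl-CoA acetyltransferase, mitochondrial precursor	5.27	2.18E-02	2.84	5	0
26	EFTU	P49411	Elongation factor Tu, mitochondrial precursor	14.88	1.14E-04	2.47	19	4
27	IDHP	P48735	Isocitrate dehydrogenase [NADP], mitochondrial precursor	13.55	2.32E-04	2.39	18	4
28	LRC47	Q8N1G4	Leucine-rich repeat-containing protein 47	5.41	2.01E-02	2.39	7	1
29	CO6A1	P12109	Collagen alpha-1(VI) chain precursor	4.08	4.34E-02	2.20	6	1
30	PSA	P55786	Puromycin-sensitive aminopeptidase	4.08	4.34E-02	2.20	6	1
31	IMB1	Q14974	Importin subunit beta-1	5.95	1.47E-02	2.17	9	2
32	PSA2	P25787	Proteasome subunit alpha type-2	4.72	2.99E-02	2.02	8	2
33	FAS	P49327	Fatty acid synthase	9.93	1.63E-03	1.93	18	6
34	A1AT	P01009	Alpha-1-antitrypsin precursor	4.05	4.41E-02	1.62	10	4
35	ROA1	P09651	Heterogeneous nuclear ribonucleoprotein A1	6.43	1.12E-02	1.58	16	7
36	FINC	P02751	Fibronectin precursor	8.01	4.64E-03	1.57	20	9
37	TRAP1	Q12931	Heat shock protein 75 kDa, mitochondrial precursor	6.26	1.24E-02	1.50	17	8
38	MYH14	Q7Z406	Myosin-14	6.26	1.24E-02	1.50	17	8
39	ANXA2	P07355	Annexin A2	5.46	1.94E-02	1.49	15	7
40	PHB2	Q99623	Prohibitin-2	4.67	3.07E-02	1.49	13	6
41	GSTP1	P09211	Glutathione S-transferase P	10.63	1.12E-03	1.38	32	17
42	PDIA1	P07237	Protein disulfide-isomerase precursor	8.96	2.76E-03	1.33	29	16
43	1433G	P61981	14-3-3 protein gamma	8.11	4.40E-03	1.28	28	16
44	ACTN4	O43707	Alpha-actinin-4	8.82	2.98E-03	1.26	31	18
45	PCBP2	Q15366	Poly(rC)-binding protein 2	5.03	2.49E-02	1.16	21	13
46	TPIS	P60174	Triosephosphate isomerase	6.45	1.11E-02	1.12	28	18
47	TRFE	P02787	Serotransferrin precursor	7.17	7.41E-03	1.12	31	20
48	ARF1	P84077	ADP-ribosylation factor 1	5.00	2.53E-02	1.09	23	15
49	PCBP1	Q15365	Poly(rC)-binding protein 1	4.31	3.79E-02	1.01	23	16
50	CO6A3	P12111	Collagen alpha-3(VI) chain precursor	5.16	2.31E-02	0.91	32	24
51	EF1A1	P68104	Elongation factor 1-alpha 1	4.72	2.98E-02	0.83	35	28
52	PDIA6	Q15084	Protein disulfide-isomerase A6 precursor	4.01	4.52E-02	0.81	31	25
53	G3P	P04406	Glyceraldehyde-3-phosphate dehydrogenase	14.21	1.64E-04	0.77	113	95
54	ENPL	P14625	Endoplasmin precursor	5.76	1.64E-02	0.66	62	56
55	TBB2A	Q13885	Tubulin beta-2A chain	5.80	1.61E-02	0.63	69	64
56	VIME	P08670	Vimentin	5.92	1.49E-02	0.60	77	73
57	HBB	P68871	Hemoglobin subunit beta	4.88	2.72E-02	-0.53	53	110
58	TBB5	P07437	Tubulin beta chain	10.89	9.64E-04	-0.63	81	179
59	TBA1A	Q71U36	Tubulin alpha-1A chain	14.38	1.49E-04	-0.67	93	211
60	TBB2B	Q9BVA1	Tubulin beta-2B chain	5.93	1.49E-02	-0.69	35	82
61	H2B1B	P33778	Histone H2B type 1-B	6.45	1.11E-02	-0.83	25	65
62	LMNB1	P20700	Lamin-B1	7.27	7.03E-03	-0.87	25	67
63	HBA	P69905	Hemoglobin subunit alpha	5.77	1.63E-02	-0.92	17	48
64	CALM	P62158	Calmodulin	3.90	4.82E-02	-1.00	9	28
65	HNRH1	P31943	Heterogeneous nuclear ribonucleoprotein H	4.36	3.67E-02	-1.01	10	31
66	NUMA1	Q14980	Nuclear mitotic apparatus protein 1	4.83	2.80E-02	-1.01	11	34
67	LAP2A	P42166	Lamina-associated polypeptide 2 isoform alpha	5.31	2.13E-02	-1.05	11	35
68	H31T	Q16695	Histone H3.1t	6.23	1.26E-02	-1.06	13	41
69	GDIA	P31150	Rab GDP dissociation inhibitor alpha	7.65	5.67E-03	-1.09	15	48
70	TBA1C	Q9BQE3	Tubulin alpha-1C chain	14.23	1.62E-04	-1.12	27	86
71	TBA1B	P68363	Tubulin alpha-1B chain	35.27	2.88E-09	-1.16	63	202
72	K1C19	P08727	Keratin, type I cytoskeletal 19	10.64	1.11E-03	-1.19	17	58
73	HSP76	P17066	Heat shock 70 kDa protein 6	6.46	1.10E-02	-1.23	9	33
74	H12	P16403	Histone H1.2	7.59	5.87E-03	-1.31	9	35
75	TBB4	P04350	Tubulin beta-4 chain	12.66	3.73E-04	-1.50	11	48
76	MOES	P26038	Moesin	4.51	3.36E-02	-1.51	3	16
77	KU70	P12956	ATP-dependent DNA helicase 2 subunit 1	22.32	2.31E-06	-1.64	16	75
78	DYHC1	Q14204	Cytoplasmic dynein 1 heavy chain 1	8.54	3.48E-03	-1.67	5	27
79	RBBP4	Q09028	Histone-binding protein RBBP4	6.58	1.03E-02	-1.74	3	19
80	PGS1	P21810	Biglycan precursor	3.99	4.59E-02	-1.81	1	10
81	ROA1L	Q32P51	Heterogeneous nuclear ribonucleoprotein A1-like protein	7.30	6.89E-03	-1.81	3	20
82	HNRPF	P52597	Heterogeneous nuclear ribonucleoprotein F	4.77	2.90E-02	-1.93	1	11
83	RUXG	P62308	Small nuclear ribonucleoprotein G	6.40	1.14E-02	-2.15	1	13
84	1433S	P31947	14-3-3 protein sigma	4.19	4.08E-02	-2.21	0	7
85	PEG10	Q86TG7	Retrotransposon-derived protein PEG10	4.19	4.08E-02	-2.21	0	7
86	CAYP1	Q13938	Calcyphosin	4.19	4.08E-02	-2.21	0	7
87	GBB1	P62873	Guanine nucleotide-binding protein G(I)/G(S)/G(T) subunit beta-1	4.19	4.08E-02	-2.21	0	7
88	NCA11	P13591	Neural cell adhesion molecule 1, 140 kDa isoform precursor	4.19	4.08E-02	-2.21	0	7
89	FSCN1	Q16658	Fascin	5.11	2.38E-02	-2.37	0	8
90	ROA0	Q13151	Heterogeneous nuclear ribonucleoprotein A0	8.98	2.74E-03	-2.43	1	16
91	MDHC	P40925	Malate dehydrogenase, cytoplasmic	7.00	8.13E-03	-2.66	0	10
92	H2A1D	P20671	Histone H2A type 1-D	8.94	2.79E-03	-2.89	0	12
93	SEGN	O76038	Secretagogin	15.915	6.63E-05	-3.51	0	19
94	MAP1B	P46821	Microtubule-associated protein 1B	16.926	3.89E-05	-3.58	0	20
95	BASP	P80723	Brain acid soluble protein 1	24.067	9.30E-07	-3.99	0	27
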