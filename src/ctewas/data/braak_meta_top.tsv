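rank	p_meta	p_neuron	p_glia	probe_id	chromosome	position	gene	region	fdr
1	1.50E-13	1.15E-06	3.83E-09	cg06549928	1	89990868	LRRC8B	5UTR	7.17624E-08
2	6.43E-11	4.64E-06	4.98E-07	cg21913630	7	128828599	SMO	TSS200	1.53811E-05
3	2.05E-10	3.04E-05	2.54E-07	cg16562251	1	166845621	TADA1	1stExon	3.26918E-05
4	2.90E-10	1.15E-05	9.63E-07	cg08738571	12	32655192	FGD4	1stExon	3.45416E-05
5	3.61E-10	9.00E-06	1.54E-06	cg22140756	2	177895827			3.45416E-05
6	4.81E-10	7.42E-06	2.52E-06	cg04913265	11	133939627	JAM3	Body	3.8353E-05
7	8.78E-10	1.69E-05	2.07E-06	cg20693608	4	113152836	AP1AR	TSS200	6.0007E-05
8	1.57E-09	7.82E-06	8.20E-06	cg24449302	15	66679100	MAP2K1	TSS200	7.02674E-05
9	1.60E-09	7.69E-06	8.51E-06	cg13172549	7	27153636	HOXA3	5UTR	7.02674E-05
10	1.61E-09	2.63E-06	2.50E-05	cg04547723	14	75421960	PGF	5UTR	7.02674E-05
11	1.67E-09	1.49E-05	4.58E-06	cg07835289	1	236030215	LYST	5UTR	7.02674E-05
15	2.27E-09	2.1772E-04	4.33E-07	cg11817993	14	92572978	ATXN3	TSS200	7.02674E-05
21	5.19E-09	3.14E-05	7.12E-06	cg02037503	14	23540729	ACIN1	1stExon	1.18237E-04
27	1.04E-08	7.43E-05	6.24E-06	cg03040740	13	99084682	FARP1	Body	1.84279E-04
32	1.44E-08	8.7784E-04	7.40E-07	cg13859639	11	2846716	KCNQ1	Body	2.15287E-04
38	2.41E-08	4.1341E-04	2.70E-06	cg03907612	6	41703314	TFEB	5UTR	3.03416E-04
39	2.60E-08	7.11E-05	1.70E-05	cg16568373	17	4853368	ENO3	TSS1500	3.18944E-04
48	3.48E-08	2.84E-05	5.76E-05	cg05884192	14	52515736	NID2	Body	3.34891E-04
53	3.75E-08	1.2506E-04	1.42E-05	cg08883485	1	201619787	NAV1	Body	3.34891E-04
58	4.55E-08	4.14E-05	5.24E-05	cg23712970	14	23540735	ACIN1	1stExon	3.74624E-04
74	6.71E-08	1.05E-05	3.106E-04	cg08843538	2	210288784	MAP2	1stExon	4.29299E-04
76	6.94E-08	4.79E-05	7.07E-05	cg04542489	14	23775746	BCL2L2	TSS1500	4.3306E-04
102	1.24E-07	4.82E-05	1.2891E-04	cg06355720	1	153333350	S100A9	3UTR	5.81604E-04
103	1.27E-07	5.37E-05	1.1905E-04	cg26327118	6	39693366	KIF6	TSS200	5.89892E-04
104	1.31E-07	1.08E-05	6.1189E-04	cg16258854	2	20648194	RHOB	1stExon	5.95763E-04
111	1.41E-07	5.2315E-04	1.36E-05	cg08866780	21	27543523	APP	TSS1500	6.04315E-04
112	1.42E-07	1.466411E-02	4.90E-07	cg03613822	17	7115140	DLG4	Body	6.04315E-04
126	1.71E-07	5.41E-06	1.61641E-03	cg06291595	14	74960292	NPC2	TSS1500	6.46609E-04
131	1.86E-07	1.071281E-02	8.90E-07	cg04153489	8	41655983	ANK1	TSS1500	6.79278E-04
133	1.99E-07	2.07E-05	4.9571E-04	cg19447671	2	176032513	ATF2	5UTR	7.15825E-04
134	2.04E-07	5.8734E-04	1.79E-05	cg10313337	16	68823690	CDH1	Body	7.28335E-04
141	2.18E-07	2.0684E-04	5.47E-05	cg01015899	12	120663812	PXN	5UTR	7.37839E-04
152	2.41E-07	2.45E-05	5.1347E-04	cg27212541	3	49507385	DAG1	TSS200	7.5801E-04
161	2.68E-07	2.7187E-04	5.17E-05	cg07745886	8	42150794	IKBKB	Body	7.96369E-04
199	4.19E-07	9.5868E-04	2.35E-05	cg01231165	2	9695142	ADAM17	Body	1.001966E-03
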