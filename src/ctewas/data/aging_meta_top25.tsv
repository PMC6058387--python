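rank	p_meta	p_neuron	p_glia	probe_id	chromosome	position	gene	region	fdr
1	4.34E-27	6.58E-09	1.00E-20	cg13327545	10	22623548			2.0763E-21
2	9.38E-26	5.55E-10	2.69E-18	cg16867657	6	11044877	ELOVL2	TSS1500	2.2438E-20
3	2.53E-25	8.99E-09	4.56E-19	cg20224218	9	129261375	FAM125B	Body	4.0346E-20
4	4.38E-25	5.03E-06	1.42E-21	cg10804656	10	22623460			5.2387E-20
5	6.46E-25	9.09E-14	1.17E-13	cg14919554	5	43018629			6.1811E-20
6	8.12E-25	2.95E-17	4.54E-10	cg02426178	19	10747142	SLC44A2	Body	6.4746E-20
7	1.65E-24	5.49E-16	5.01E-11	cg03984866	4	8161776	ABLIM2	TSS1500	1.0465E-19
8	1.75E-24	1.52E-09	1.92E-17	cg10906284	12	63544430	AVPR1A	1stExon	1.0465E-19
9	2.38E-24	2.13E-06	1.88E-20	cg17117277	19	3822126	ZFR2	Body	1.2651E-19
10	5.41E-24	2.75E-08	3.36E-18	cg06022942	10	8095484	FLJ45983	TSS200	2.5882E-19
11	7.95E-24	3.53E-14	3.86E-12	ch.6.1693624F	6	83767401	UBE2CBP	Body	3.4576E-19
12	1.32E-23	5.62E-09	4.06E-17	cg24954207	3	128217091			5.2626E-19
13	1.77E-23	4.00E-09	7.68E-17	cg08234504	5	139013317			6.5138E-19
14	1.92E-23	8.17E-11	4.10E-15	cg02492920	7	150659969	KCNH2	Body	6.5384E-19
15	2.05E-23	1.01E-11	3.53E-14	cg14299508	8	105907690			6.5384E-19
16	3.75E-23	2.50E-12	2.64E-13	cg08594681	8	27468684	CLU	1stExon	1.1213E-18
17	4.63E-23	6.45E-14	1.27E-11	cg08342886	6	33240066	VPS52	TSS1500	1.303E-18
18	1.20E-22	9.22E-10	2.34E-15	cg00303378	1	159825552	VSIG8	Body	3.0971E-18
19	1.23E-22	1.21E-10	1.83E-14	cg23813012	1	14026482	PRDM2	TSS1500	3.0971E-18
20	1.38E-22	5.01E-10	4.98E-15	ch.13.22912778R	13	24014778			3.2806E-18
21	1.44E-22	1.20E-08	2.17E-16	cg06639320	2	106015739	FHL2	TSS200	3.2806E-18
22	1.77E-22	1.31E-09	2.45E-15	cg15393490	1	207996459			3.8491E-18
23	1.90E-22	6.33E-08	5.46E-17	cg26880525	1	209877941	HSD11B1	5UTR	3.8672E-18
24	1.94E-22	6.83E-13	5.17E-12	cg04211309	16	58056296			3.8672E-18
25	2.33E-22	5.12E-15	8.29E-10	cg09131339	1	109914235	SORT1	Body	4.4588E-18
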