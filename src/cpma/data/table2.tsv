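SNP	CHR	POS	major_al	minor_al	Genes	Panel	Reference	Disease	Disease_inferred	RA.Z	RA.P	PS.Z	PS.P	MS.Z	MS.P	SLE.Z	SLE.P	CD.Z	CD.P	CeD.Z	CeD.P	T1D.Z	T1D.P	cpma.p
rs10889677	1	67437141	C	A	IL23R	upper	37	NA	0	0.0	9.8E-01	5.1	3.5E-07	-2.6	4.9E-03	-0.3	6.2E-01	10.3	9.0E-25	1.1	8.7E-01	0.1	5.3E-01	6.9E-25
rs3087243	2	204564425	G	A	CTLA4	upper	36	NA	0	-5.7	1.2E-08	0.3	8.0E-01	-0.7	2.5E-01	-0.5	3.0E-01	-1.2	2.3E-01	2.9	2.2E-03	-8.5	1.1E-17	2.8E-21
rs2542151	18	12769947	T	G	PTPN2	upper	1	CD	0	4.2	3.0E-05	2.0	4.1E-02	-0.8	2.2E-01	1.1	1.5E-01	6.8	1.2E-11	4.8	6.9E-07	7.1	5.9E-13	5.3E-19
rs2201841	1	67406223	A	G	IL23R	upper	5	PS	0	0.0	9.9E-01	5.2	2.7E-07	-2.2	1.3E-02	-0.3	6.3E-01	9.9	3.5E-23	1.0	8.4E-01	0.2	5.7E-01	3.7E-18
rs11209032	1	67452113	G	A	IL23R	upper	33	NA	0	-0.6	5.2E-01	5.3	1.3E-07	-1.2	1.2E-01	-0.7	2.3E-01	8.4	3.1E-17	1.2	8.8E-01	0.2	4.4E-01	6.4E-18
rs1893217	18	12799340	A	G	PTPN2	upper	24	T1D	0	4.2	2.4E-05	2.1	3.9E-02	-0.6	2.8E-01	1.0	1.5E-01	6.5	6.5E-11	4.9	6.1E-07	7.4	8.2E-14	3.4E-17
rs917997	2	102529086	C	T	IL18RAP	upper	3	NA	0	0.3	7.8E-01	-0.2	8.8E-01	0.3	3.7E-01	1.1	1.3E-01	4.2	2.2E-05	7.6	1.1E-14	-1.5	9.4E-01	4.9E-13
rs12708716	16	11087374	A	G	CLEC16A	upper	32	MS	1	0.2	8.3E-01	-0.3	8.1E-01	3.7	1.1E-04	-1.0	1.5E-01	-0.6	5.5E-01	1.6	5.3E-02	-8.2	1.2E-16	2.0E-12
rs2872507	17	35294289	G	A	ORMDL3	upper	1	CD	0	4.1	4.7E-05	0.3	8.0E-01	-3.3	5.5E-04	-0.3	6.3E-01	4.7	2.1E-06	0.7	7.6E-01	5.0	2.5E-07	4.1E-09
rs3821236	2	191728264	G	A	STAT4	upper	2	NA	0	4.7	2.5E-06	-1.7	9.5E-02	0.1	4.6E-01	6.2	2.1E-10	-1.7	9.6E-02	1.9	3.1E-02	3.4	3.5E-04	9.8E-08
rs6441961	3	46327388	C	T	CCR1	upper	3	NA	0	1.1	2.7E-01	-0.3	7.5E-01	0.1	4.7E-01	1.3	9.1E-01	-0.5	6.1E-01	5.7	6.9E-09	3.7	1.0E-04	1.9E-07
rs2290400	17	35319766	C	T	ORMDL3	upper	24	T1D	0	-3.9	1.1E-04	0.4	7.2E-01	3.3	5.5E-04	0.2	5.7E-01	3.7	2.4E-04	0.2	4.1E-01	-5.1	1.4E-07	1.2E-06
rs7197475	16	30550368	C	T	16p11.2	upper	35	NA	0	2.9	3.8E-03	2.9	4.3E-03	-0.9	1.7E-01	0.7	2.4E-01	-4.2	2.5E-05	0.4	3.4E-01	-0.9	1.9E-01	2.0E-06
rs4917014	7	50083124	T	G	IKZF1	upper	35	NA	0	-2.5	1.3E-02	0.9	3.8E-01	3.5	2.6E-04	-2.9	1.9E-03	1.6	1.1E-01	0.9	1.8E-01	-3.3	5.2E-04	4.9E-06
rs6822844	4	123867026	G	T	IL2-IL21	upper	38	NA	0	-3.4	6.5E-04	-1.7	8.7E-02	1.2	1.1E-01	-0.2	4.3E-01	-2.4	1.5E-02	3.3	4.9E-04	-1.1	1.5E-01	6.2E-06
rs10517086	4	25761780	G	A	4p15.2	upper	24	T1D	0	5.1	2.8E-07	0.6	5.7E-01	0.4	3.6E-01	0.1	5.5E-01	2.8	5.5E-03	0.2	5.6E-01	4.9	5.7E-07	2.3E-05
rs11203203	21	42709255	G	A	UBASH3A	upper	24	T1D	0	4.2	2.5E-05	1.3	1.9E-01	0.2	4.4E-01	1.6	5.3E-02	0.0	9.8E-01	3.1	1.0E-03	6.6	1.8E-11	2.5E-05
rs4728142	7	128167918	G	A	IRF5	upper	35	NA	0	4.5	7.1E-06	1.4	1.8E-01	-1.5	6.4E-02	6.2	2.9E-10	0.8	4.4E-01	2.1	1.6E-02	-0.2	4.1E-01	4.4E-05
rs11755527	6	91014952	C	G	BACH2	upper	24	T1D	0	-1.4	1.6E-01	-0.7	5.1E-01	-2.8	2.7E-03	1.0	8.5E-01	-2.6	1.0E-02	3.5	2.8E-04	5.6	1.0E-08	8.0E-05
rs7709212	5	158696755	T	C	IL12B	upper	39	NA	0	-0.6	5.7E-01	-6.3	3.8E-10	3.6	1.9E-04	-2.3	1.1E-02	3.3	9.8E-04	0.1	5.5E-01	1.2	8.9E-01	8.8E-05
rs947474	10	6430456	A	G	PRKCQ	upper	34	NA	0	-4.4	8.7E-06	-1.0	3.4E-01	-0.3	6.3E-01	-1.0	8.5E-01	-2.4	1.9E-02	2.0	2.1E-02	-3.7	1.1E-04	9.1E-05
rs2188962	5	131798704	C	T	5q31	upper	1	CD	0	-0.3	7.7E-01	3.0	3.2E-03	1.3	9.6E-02	1.5	7.0E-02	5.9	4.6E-09	1.8	3.7E-02	2.9	2.0E-03	1.6E-04
rs744166	17	37767727	A	G	STAT3	upper	1	CD	0	-0.7	4.7E-01	1.3	1.9E-01	-4.4	6.4E-06	0.7	7.6E-01	-4.5	5.9E-06	2.2	9.8E-01	-2.6	4.6E-03	2.2E-04
rs4788084	16	28447349	C	T	IL27	upper	24	T1D	0	2.6	1.0E-02	1.3	2.1E-01	0.3	6.1E-01	1.3	9.1E-02	2.9	3.5E-03	2.3	1.1E-02	-6.5	5.1E-11	4.1E-04
rs2082412	5	158650367	G	A	IL12B	upper	5	PS	0	-1.2	2.3E-01	-6.2	8.8E-10	NA	NA	-3.8	7.1E-05	2.6	9.6E-03	0.4	3.6E-01	0.0	5.0E-01	4.6E-04
rs11465804	1	67414547	T	G	IL23R	upper	1	CD	0	-0.4	6.8E-01	-4.9	1.3E-06	-1.7	9.5E-01	-0.4	3.6E-01	-12.5	1.0E-35	1.2	1.2E-01	-1.0	1.6E-01	5.2E-04
rs463426	22	20133739	C	T	HIC2-UBE2L3	upper	35	NA	0	2.2	2.9E-02	1.4	1.6E-01	1.0	1.7E-01	0.3	3.7E-01	1.8	6.7E-02	3.3	4.1E-04	0.5	2.9E-01	5.2E-04
rs763361	18	65682622	C	T	CD226	upper	24	T1D	0	2.1	3.3E-02	1.9	6.5E-02	-1.7	4.5E-02	0.0	4.9E-01	2.0	4.1E-02	2.5	6.7E-03	5.1	1.6E-07	9.0E-04
rs11584383	1	197667523	T	C	KIF21B	upper	1	CD	0	2.3	2.3E-02	0.0	9.7E-01	3.3	4.6E-04	-0.3	6.2E-01	-5.0	6.8E-07	0.8	2.0E-01	-2.3	1.0E-02	9.0E-04
rs6590330	11	127816269	G	A	ETS1	upper	35	NA	0	3.2	1.5E-03	-0.5	6.0E-01	-2.7	3.7E-03	2.1	1.9E-02	0.6	5.2E-01	1.4	9.2E-01	1.8	3.9E-02	2.6E-03
rs4900384	14	97568704	A	G	14q32.2	upper	24	T1D	0	1.3	2.0E-01	0.8	4.4E-01	1.8	3.9E-02	-1.9	3.0E-02	0.2	8.1E-01	3.2	7.6E-04	5.2	8.9E-08	2.8E-03
rs10758669	9	4971602	A	C	JAK2	upper	1	CD	0	1.0	3.3E-01	1.2	2.4E-01	-3.3	4.2E-04	0.3	4.0E-01	5.0	6.8E-07	1.8	3.7E-02	1.0	1.7E-01	3.4E-03
rs1913517	10	49789060	A	G	LRRC18-WDFY4	upper	35	NA	0	-4.4	1.1E-05	0.8	4.4E-01	0.4	3.5E-01	-2.4	8.7E-03	-0.4	6.9E-01	0.1	4.4E-01	-0.8	2.2E-01	4.1E-03
rs4505848	4	123490097	A	G	IL2	upper	24	T1D	0	-0.5	6.0E-01	0.1	9.0E-01	0.5	7.0E-01	1.1	1.3E-01	3.0	2.6E-03	3.1	9.6E-04	6.6	2.3E-11	4.4E-03
rs7804356	7	26664905	T	C	7p15.2	upper	24	T1D	0	-1.3	1.9E-01	1.2	2.2E-01	1.0	1.5E-01	-0.1	4.8E-01	3.4	5.9E-04	1.3	9.9E-02	-5.6	9.5E-09	5.6E-03
rs11258747	10	6512897	G	T	PRKCQ	upper	24	T1D	0	3.0	2.4E-03	1.9	6.0E-02	-2.5	6.7E-03	0.6	7.3E-01	0.1	9.2E-01	0.2	4.2E-01	4.8	7.7E-07	7.5E-03
rs703842	12	56449006	A	G	CYP27B1	upper	31	NA	0	-2.7	6.1E-03	-0.1	8.9E-01	4.1	1.7E-05	-0.4	6.7E-01	-1.1	2.5E-01	2.0	2.3E-02	-2.2	1.5E-02	8.3E-03
rs1990760	2	162949558	T	C	IFIH1	upper	24	T1D	0	-1.0	3.0E-01	-2.4	1.7E-02	0.1	5.4E-01	-3.4	3.2E-04	0.6	5.6E-01	0.4	6.5E-01	-6.2	2.5E-10	8.6E-03
rs2476601	1	114089610	G	A	PTPN22	lower	1	CD	0	18.2	9.1E-74	0.0	1.0E+00	0.4	3.5E-01	4.0	3.3E-05	-4.3	1.8E-05	1.7	4.2E-02	20.4	1.5E-92	6.3E-160
rs3184504	12	110347328	T	C	SH2B3	lower	24	T1D	0	-2.9	3.6E-03	-2.0	4.1E-02	3.4	3.3E-04	-2.7	3.6E-03	-3.4	6.2E-04	7.3	1.2E-13	-11.9	7.7E-33	4.3E-19
rs11865121	16	11074189	C	A	CLEC16A	lower	4	MS	0	0.3	7.7E-01	0.6	5.2E-01	4.3	8.7E-06	-0.7	2.3E-01	0.9	3.8E-01	1.1	1.4E-01	-8.9	2.1E-19	1.1E-14
rs2816316	1	189268470	A	C	RGS1	lower	3	NA	0	-1.0	3.3E-01	-0.4	6.7E-01	3.1	9.0E-04	-0.1	5.3E-01	-0.5	6.4E-01	6.9	2.7E-12	-3.9	4.2E-05	5.2E-13
rs2104286	10	6139051	T	C	IL2RA	lower	32	NA	0	-3.1	1.8E-03	-0.1	9.5E-01	6.2	3.5E-10	0.4	6.5E-01	-0.8	4.4E-01	0.5	3.1E-01	-6.4	5.9E-11	1.2E-08
rs3024505	1	203328299	G	A	IL10	lower	23	SLE	0	-1.0	3.3E-01	0.9	3.8E-01	1.5	7.3E-02	4.2	1.3E-05	2.4	1.6E-02	1.6	5.4E-02	-4.8	6.2E-07	2.2E-06
rs10045431	5	158747111	C	A	IL12B	lower	1	CD	0	0.4	6.5E-01	4.5	6.6E-06	0.3	6.3E-01	2.4	8.8E-03	-5.8	8.8E-09	0.5	6.8E-01	0.1	4.6E-01	6.0E-04
rs610604	6	138241110	T	G	TNFAIP3	lower	5	PS	0	-4.2	3.3E-05	4.5	8.0E-06	0.3	3.8E-01	-1.3	9.9E-02	1.4	1.8E-01	0.4	6.5E-01	-0.2	4.3E-01	2.7E-03
rs4613763	5	40428485	T	C	PTGER4	lower	1	CD	0	0.9	3.9E-01	0.7	4.7E-01	-4.2	1.1E-05	0.4	3.4E-01	9.6	5.0E-22	0.1	5.2E-01	-0.5	3.1E-01	4.0E-03
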