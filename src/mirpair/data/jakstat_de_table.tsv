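gene	mean_carcinoma	mean_normal	fc	p_raw	p_adj	printed_bold
AKT1	153.83	152.34	1.01	0.708	0.738	0
AKT2	156.81	135.87	1.15	<0.001	<0.001	0
AKT3	41.45	52.56	0.79	<0.001	<0.001	0
AOX1	3.69	8.86	0.42	<0.001	<0.001	1
BCL2	24.42	62.11	0.39	<0.001	<0.001	1
BCL2L1	144.28	64.05	2.25	<0.001	<0.001	1
CCND1	317.79	122.64	2.59	<0.001	<0.001	1
CCND2	773.45	483.06	1.60	<0.001	<0.001	1
CCND3	33.57	40.72	0.82	<0.001	<0.001	0
CDKN1A	84.50	98.10	0.86	0.004	0.006	0
CISH	30.23	36.72	0.82	<0.001	<0.001	0
CNTF	3.26	4.86	0.67	<0.001	<0.001	0
CNTFR	0.73	4.85	0.15	<0.001	<0.001	1
CREBBP	264.23	273.44	0.97	0.061	0.079	0
CSF2RA	3.29	3.37	0.98	0.880	0.887	0
CSF2RB	27.82	73.57	0.38	<0.001	<0.001	1
CSF3	1.03	1.66	0.62	0.009	0.013	1
CSF3R	25.53	24.64	1.04	0.619	0.674	0
CTF1	1.33	1.11	1.20	0.254	0.302	0
EP300	293.90	339.29	0.87	<0.001	<0.001	0
EPOR	6.81	10.87	0.63	<0.001	<0.001	1
FHL1	21.10	96.69	0.22	<0.001	<0.001	1
GFAP	0.46	0.55	0.84	0.308	0.351	0
GHR	6.68	20.21	0.33	<0.001	<0.001	1
GRB2	114.66	112.16	1.02	0.407	0.455	0
HRAS	18.52	12.37	1.50	<0.001	<0.001	0
IFNAR1	100.68	99.38	1.01	0.675	0.716	0
IFNAR2	49.46	53.08	0.93	0.044	0.060	0
IFNE	0.65	0.36	1.83	0.038	0.052	0
IFNG	0.78	2.48	0.32	<0.001	<0.001	1
IFNGR1	49.74	44.34	1.12	0.004	0.006	0
IFNGR2	71.20	57.91	1.23	<0.001	<0.001	0
IFNK	5.85	11.76	0.50	<0.001	<0.001	1
IL10	0.82	1.04	0.79	0.137	0.173	0
IL10RA	47.02	118.37	0.40	<0.001	<0.001	1
IL10RB	38.15	54.43	0.70	<0.001	<0.001	0
IL11	4.99	1.58	3.16	<0.001	<0.001	1
IL11RA	11.35	21.84	0.52	<0.001	<0.001	1
IL12A	0.66	0.94	0.71	0.049	0.065	0
IL12B	0.30	0.49	0.62	0.068	0.087	0
IL12RB1	5.54	7.02	0.79	0.019	0.028	0
IL12RB2	6.45	6.76	0.95	0.575	0.632	0
IL13	0.21	0.58	0.36	<0.001	<0.001	1
IL13RA1	185.64	145.89	1.27	<0.001	<0.001	0
IL13RA2	0.30	0.52	0.58	0.037	0.051	0
IL15	17.83	28.58	0.62	<0.001	<0.001	1
IL15RA	18.50	15.76	1.17	0.008	0.012	0
IL17D	12.16	4.99	2.44	<0.001	<0.001	1
IL19	0.20	0.34	0.60	0.047	0.063	0
IL20RA	30.28	12.37	2.45	<0.001	<0.001	1
IL20RB	4.98	6.23	0.80	0.004	0.006	0
IL21R	8.58	10.26	0.84	0.048	0.064	0
IL22RA1	40.43	33.11	1.22	0.001	0.002	0
IL22RA2	0.32	0.66	0.48	0.003	0.004	1
IL23A	2.06	1.59	1.30	0.036	0.051	0
IL23R	2.97	5.83	0.51	<0.001	<0.001	1
IL24	3.15	8.15	0.39	<0.001	<0.001	1
IL27RA	10.05	10.24	0.98	0.817	0.838	0
IL28RA	26.18	31.15	0.84	0.002	0.004	0
IL2RA	7.04	6.38	1.10	0.280	0.325	0
IL2RB	17.40	20.32	0.86	0.034	0.048	0
IL2RG	44.20	50.55	0.87	0.027	0.039	0
IL3RA	2.21	3.59	0.62	0.003	0.005	1
IL4R	114.37	143.74	0.80	<0.001	<0.001	0
IL5	1.26	2.00	0.63	0.001	0.002	1
IL5RA	0.49	1.94	0.25	<0.001	<0.001	1
IL6	4.04	3.08	1.31	0.062	0.079	0
IL6R	25.93	101.24	0.26	<0.001	<0.001	1
IL6ST	166.16	281.27	0.59	<0.001	<0.001	1
IL7	15.39	15.71	0.98	0.741	0.766	0
IL7R	35.03	79.98	0.44	<0.001	<0.001	1
IRF9	61.65	61.12	1.01	0.839	0.853	0
JAK1	200.53	198.85	1.01	0.701	0.738	0
JAK2	46.91	57.44	0.82	<0.001	<0.001	0
JAK3	47.72	66.78	0.71	<0.001	<0.001	0
LEP	0.87	1.16	0.75	0.152	0.189	0
LEPR	11.97	14.69	0.81	0.004	0.006	0
LIF	75.84	44.62	1.70	<0.001	<0.001	1
LIFR	13.28	59.86	0.22	<0.001	<0.001	1
MCL1	615.27	794.46	0.77	<0.001	<0.001	0
MPL	0.90	1.60	0.56	<0.001	<0.001	1
MTOR	172.49	189.52	0.91	0.001	0.002	0
MYC	181.11	49.00	3.70	<0.001	<0.001	1
OSM	6.68	2.31	2.90	<0.001	<0.001	1
OSMR	39.06	47.83	0.82	<0.001	<0.001	0
PIAS1	38.62	47.06	0.82	<0.001	<0.001	0
PIAS2	26.48	37.23	0.71	<0.001	<0.001	0
PIAS3	36.31	34.92	1.04	0.357	0.403	0
PIAS4	29.27	35.75	0.82	<0.001	<0.001	0
PIK3CA	67.11	55.23	1.22	<0.001	<0.001	0
PIK3CB	90.89	81.36	1.12	0.001	0.001	0
PIK3CD	27.33	46.48	0.59	<0.001	<0.001	1
PIK3R1	154.42	149.09	1.04	0.300	0.345	0
PIK3R2	72.83	54.55	1.34	<0.001	<0.001	0
PIK3R3	35.88	33.87	1.06	0.255	0.302	0
PIM1	38.42	42.83	0.90	0.030	0.044	0
PRLR	100.62	93.37	1.08	0.216	0.264	0
PTPN11	227.06	116.88	1.94	<0.001	<0.001	1
PTPN2	31.73	31.08	1.02	0.674	0.716	0
PTPN6	38.91	47.34	0.82	<0.001	<0.001	0
RAF1	131.53	147.29	0.89	<0.001	<0.001	0
SOCS1	4.19	3.98	1.05	0.552	0.612	0
SOCS2	7.99	13.77	0.58	<0.001	<0.001	1
SOCS3	67.43	81.65	0.83	0.001	0.002	0
SOCS4	63.55	54.54	1.17	<0.001	<0.001	0
SOCS5	37.44	32.53	1.15	<0.001	0.001	0
SOCS6	47.54	69.67	0.68	<0.001	<0.001	0
SOCS7	22.20	14.71	1.51	<0.001	<0.001	1
SOS1	159.37	164.61	0.97	0.224	0.270	0
SOS2	91.40	127.77	0.72	<0.001	<0.001	0
STAM	35.53	26.52	1.34	<0.001	<0.001	0
STAM2	60.45	73.55	0.82	<0.001	<0.001	0
STAT1	341.01	220.37	1.55	<0.001	<0.001	1
STAT2	159.86	162.27	0.99	0.642	0.693	0
STAT3	228.06	249.88	0.91	<0.001	<0.001	0
STAT4	7.35	14.04	0.52	<0.001	<0.001	1
STAT5A	37.96	38.02	1.00	0.974	0.974	0
STAT5B	96.43	93.35	1.03	0.278	0.325	0
STAT6	257.47	264.74	0.97	0.176	0.217	0
THPO	0.58	1.00	0.58	0.006	0.009	1
TSLP	0.64	0.97	0.66	0.033	0.047	1
TYK2	124.25	147.05	0.84	<0.001	<0.001	0
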