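accession	name	A	R	N	D	C	Q	E	G	H	I	L	K	M	F	P	S	T	W	Y	V
GRAR740102	Polarity (Grantham, 1974)	8.1	10.5	11.6	13.0	5.5	10.5	12.3	9.0	10.4	5.2	4.9	11.3	5.7	5.2	8.0	9.2	8.6	5.4	6.2	5.9
GRAR740103	Volume (Grantham, 1974)	31	124	56	54	55	85	83	3	96	111	111	119	105	132	32.5	32	61	170	136	84
KYTJ820101	Hydropathy index (Kyte-Doolittle, 1982)	1.8	-4.5	-3.5	-3.5	2.5	-3.5	-3.5	-0.4	-3.2	4.5	3.8	-3.9	1.9	2.8	-1.6	-0.8	-0.7	-0.9	-1.3	4.2
HOPT810101	Hydrophilicity value (Hopp-Woods, 1981)	-0.5	3.0	0.2	3.0	-1.0	0.2	3.0	0.0	-0.5	-1.8	-1.8	3.0	-1.3	-2.5	0.0	0.3	-0.4	-3.4	-2.3	-1.5
ZIMJ680103	Polarity (Zimmerman, 1968)	0.00	52.00	3.38	49.70	1.48	3.53	49.90	0.00	51.60	0.13	0.13	49.50	1.43	0.35	1.58	1.67	1.66	2.10	1.61	0.13
ZIMJ680104	Isoelectric point (Zimmerman, 1968)	6.00	10.76	5.41	2.77	5.05	5.65	3.22	5.97	7.59	6.02	5.98	9.74	5.74	5.48	6.30	5.68	5.66	5.89	5.66	5.96
KLEP840101	Net charge (Klein, 1984)	0	1	0	-1	0	0	-1	0	0	0	0	1	0	0	0	0	0	0	0	0
FAUJ880111	Positive charge (Fauchere, 1988)	0	1	0	0	0	0	0	0	1	0	0	1	0	0	0	0	0	0	0	0
FAUJ880112	Negative charge (Fauchere, 1988)	0	0	0	1	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0
JOND750102	pK (-COOH) (Jones, 1975)	2.34	2.17	2.02	1.88	1.96	2.17	2.19	2.34	1.82	2.36	2.36	2.18	2.28	1.83	1.99	2.21	2.11	2.38	2.20	2.32
FASG760101	Molecular weight (Fasman, 1976)	89.09	174.20	132.12	133.10	121.15	146.15	147.13	75.07	155.16	131.17	131.17	146.19	149.21	165.19	115.13	105.09	119.12	204.23	181.19	117.15
CHOP780201	Normalized frequency of alpha-helix (Chou-Fasman, 1978)	1.42	0.98	0.67	1.01	0.70	1.11	1.51	0.57	1.00	1.08	1.21	1.16	1.45	1.13	0.57	0.77	0.83	1.08	0.69	1.06
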