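compound_id	name	herb_source	mw	alogp	hdon	hacc	ob	caco2	dl	rbn
5319744	3'-O-Methylorobol	AM	300.26	2.05	3	6	57.41	0.45	0.27	2
5281605	Baicalein	AM	270.24	2.33	3	5	33.52	0.63	0.21	1
5280448	Calycosin	AM	284.26	2.32	2	5	47.75	0.52	0.24	2
5280378	Formononetin	AM	268.26	2.58	1	4	69.67	0.78	0.21	2
72281	Hesperetin	AM	302.28	2.28	3	6	70.31	0.37	0.27	2
5281628	Hispidulin	AM	300.26	2.32	3	6	30.97	0.48	0.27	2
5281654	Isorhamnetin	AM	316.26	1.76	4	7	49.60	0.31	0.31	2
5280863	Kaempferol	AM	286.24	1.77	4	6	41.88	0.26	0.24	1
5318869	Kumatakenin	AM	314.29	2.09	2	6	50.83	0.61	0.29	3
114829	Liquiritigenin	AM	256.25	2.57	2	4	32.76	0.51	0.18	1
336327	Medicarpin	AM	270.28	2.66	1	4	49.22	1.00	0.34	1
471722	Mosloflavone	AM	298.29	2.84	1	5	34.04	0.86	0.26	3
13965473	Odoratin	AM	314.29	2.3	2	6	49.95	0.42	0.30	3
5281803	Pratensein	AM	300.26	1.37	2	6	39.06	0.39	0.28	2
5281703	Wogonin	AM	284.26	2.59	2	5	30.68	0.79	0.23	2
334704	Marmesin	AG	246.26	2.03	1	4	50.28	0.52	0.18	1
5280666	Chrysoeriol	TK	300.26	2.32	3	6	35.85	0.39	0.27	2
5281612	Diosmetin	TK	300.26	2.32	3	6	31.14	0.46	0.27	2
5280445	Luteolin	TK	286.24	2.07	4	6	36.16	0.19	0.25	1
5318214	7-O-Methylluteolin	TK	300.26	2.32	3	6	36.47	0.52	0.27	2
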