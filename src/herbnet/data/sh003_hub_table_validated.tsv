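gene	degree	betweenness	closeness
TP53	148	0.15135	0.59316
AKT1	114	0.06646	0.56934
JUN	108	0.05402	0.55714
IL6	104	0.05594	0.53793
STAT3	102	0.04319	0.54545
EGFR	100	0.04684	0.55319
ESR1	88	0.07330	0.54355
MAPK3	86	0.02919	0.52000
CASP3	84	0.02055	0.50814
IL1B	82	0.03133	0.51656
SRC	82	0.01311	0.51656
NFKB1	82	0.02687	0.52349
CCND1	82	0.03380	0.52525
HSP90AA1	82	0.03791	0.50000
FN1	78	0.04886	0.49057
MAPK1	76	0.02645	0.51148
MAPK8	72	0.01777	0.50649
INS	70	0.04570	0.50000
FOS	62	0.01344	0.48750
MAPK14	60	0.00913	0.48148
PPARG	60	0.02096	0.49057
ERBB2	58	0.03464	0.50323
MMP9	58	0.00992	0.48297
MTOR	58	0.00824	0.48148
PTGS2	58	0.03742	0.48148
GSK3B	56	0.00732	0.47273
FOXO1	56	0.01969	0.48750
IGF1	56	0.00684	0.47130
RELA	56	0.02063	0.48447
TLR4	52	0.01024	0.47706
BCL2L1	52	0.00407	0.46847
PARP1	48	0.02031	0.46018
CDK2	46	0.00983	0.44193
IRS1	44	0.00280	0.46988
CASP9	44	0.00367	0.45748
APP	44	0.04140	0.45882
CCNB1	42	0.00851	0.43575
CDH1	42	0.00204	0.45748
CDK1	42	0.00827	0.43454
MAPK9	42	0.00432	0.44571
NFE2L2	40	0.01331	0.46018
MMP2	38	0.00419	0.44193
CDK4	38	0.00434	0.44068
MCL1	34	0.01074	0.43454
MAP2K1	34	0.00177	0.44068
SMAD2	32	0.00761	0.45087
KDR	32	0.00333	0.43697
PTK2	32	0.00252	0.44571
ESR2	32	0.00523	0.45087
HMOX1	30	0.00648	0.44068
CCNA2	30	0.00192	0.41270
MMP3	28	0.00523	0.40206
AURKA	28	0.00435	0.43094
CYP1A1	28	0.04861	0.39898
NOS3	26	0.00416	0.42507
CYP19A1	26	0.06300	0.42276
HSPA8	26	0.01106	0.44699
CHEK1	26	0.00177	0.40206
AGT	24	0.00746	0.42391
CDK5	22	0.00507	0.42049
CDK6	22	0.00184	0.41711
KEAP1	20	0.00489	0.43213
GSTP1	20	0.02364	0.41935
NQO1	18	0.01164	0.43213
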