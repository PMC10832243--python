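gene	degree	betweenness	closeness
TP53	162	0.10566	0.54523
JUN	138	0.07476	0.53846
AKT1	138	0.05411	0.53056
STAT3	130	0.03249	0.51544
MAPK3	130	0.04915	0.52670
HSP90AA1	118	0.04699	0.51300
MAPK1	118	0.03560	0.51059
SRC	116	0.03600	0.50820
MYC	110	0.02469	0.49543
IL6	100	0.03790	0.49206
EGFR	100	0.04443	0.50115
CASP3	96	0.02424	0.48984
RELA	94	0.02887	0.49206
KRAS	92	0.01626	0.46667
ESR1	92	0.04012	0.49543
VEGFA	84	0.01507	0.48009
CCND1	84	0.00941	0.46269
MAPK8	78	0.01431	0.47903
IL1B	76	0.02354	0.46767
MAPK14	74	0.00708	0.45975
INS	74	0.02426	0.47797
FOS	72	0.01245	0.45877
NFKBIA	72	0.01884	0.48009
NFKB1	68	0.00743	0.45021
MTOR	66	0.00600	0.45493
FN1	64	0.01797	0.42970
STAT1	62	0.00371	0.45975
IGF1	62	0.00898	0.44286
CDK1	58	0.01181	0.43927
CDK2	58	0.00870	0.43313
FOXO1	58	0.00980	0.45114
PPARG	58	0.01106	0.46567
ERBB2	56	0.01331	0.46467
IRS1	56	0.00310	0.44016
TLR4	54	0.00806	0.44835
MMP9	54	0.01797	0.45781
PTGS2	54	0.05750	0.47797
BCL2L1	54	0.00259	0.43056
CDH1	54	0.01497	0.43662
RB1	52	0.00502	0.44650
PRKCD	50	0.00157	0.42801
NOTCH1	50	0.00650	0.44376
MAP2K1	50	0.00621	0.43487
RXRA	50	0.05300	0.46368
PTK2	48	0.00349	0.42970
PRKCA	48	0.01431	0.44467
CDK4	48	0.00353	0.42136
CASP8	48	0.00297	0.43141
GSK3B	48	0.00250	0.43227
CCL2	48	0.01312	0.42717
IGF1R	46	0.00169	0.43400
CHUK	46	0.00306	0.42633
CCNB1	46	0.00326	0.40185
APP	46	0.02875	0.43056
NOS3	44	0.01364	0.44106
SMAD2	42	0.00729	0.43662
PDPK1	40	0.00211	0.41333
NOS2	40	0.00419	0.44650
CCNA2	40	0.00202	0.39599
CDK6	38	0.00225	0.41333
H2AFX	38	0.00236	0.40789
CDK5	38	0.00274	0.41333
ESR2	38	0.00615	0.44742
ATM	38	0.00176	0.41176
MMP2	38	0.00342	0.41098
PPARA	38	0.03269	0.45877
NFATC1	36	0.00232	0.40561
HMOX1	36	0.01348	0.43141
PARP1	34	0.01929	0.41333
CAT	34	0.01341	0.43056
EZH2	30	0.00241	0.43487
HSPA8	30	0.00507	0.43662
NFE2L2	28	0.00473	0.42300
KEAP1	26	0.00424	0.42136
AHR	26	0.01433	0.42218
AURKA	24	0.00195	0.39599
GSTP1	24	0.02367	0.40789
NR1I2	24	0.02153	0.43056
HMGB1	22	0.00158	0.41021
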