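locus_id	gene	gene_class	region	motif	motif_length	is_b5	size_min	size_max
BAT25		NONE	NA	T	1	1	110	130
BAT26		NONE	NA	A	1	1	100	120
D2S123		NONE	NA	CA	2	1	197	227
D5S346		NONE	NA	CA	2	1	96	122
D17S250		NONE	NA	CA	2	1	140	170
TP53-1	TP53	TS	INTRON	AAAAT	5	0	130	180
TP53-2	TP53	TS	INTRON	CA	2	0	150	180
TP53-3	TP53	TS	INTRON	TG	2	0	200	230
P21	CDKN1A	TS	INTRON	CA	2	0	120	150
P21-2	CDKN1A	TS	INTRON	CAG	3	0	160	190
ATM-1	ATM	TS	INTRON	CA	2	0	140	170
ATM-2	ATM	TS	INTRON	AAT	3	0	180	210
ATM-3	ATM	TS	INTRON	GT	2	0	110	140
ATM-4	ATM	TS	INTRON	AAAG	4	0	220	260
APC-2	APC	TS	INTRON	CA	2	0	130	160
APC-6	APC	TS	INTRON	TG	2	0	170	200
APC-9	APC	TS	INTRON	GATA	4	0	240	280
APC-11	APC	TS	INTRON	AAAG	4	0	190	230
MCC-2	MCC	TS	INTRON	CA	2	0	100	130
MCC-3	MCC	TS	INTRON	CA	2	0	150	180
MCC-7	MCC	TS	INTRON	CAG	3	0	200	230
MCC-10	MCC	TS	INTRON	TG	2	0	120	150
MCC-14	MCC	TS	INTRON	GATA	4	0	250	290
MCC-25	MCC	TS	INTRON	CA	2	0	140	170
MCC-26	MCC	TS	INTRON	AC	2	0	180	210
BBC3-1	BBC3	TS	INTRON	CA	2	0	110	140
BBC3-2	BBC3	TS	NONCODING	AAAG	4	0	210	250
PTEN-1	PTEN	TS	INTRON	CA	2	0	130	160
PTEN-2	PTEN	TS	INTRON	TG	2	0	160	190
PTEN-3	PTEN	TS	INTRON	GATA	4	0	230	270
PTEN-4	PTEN	TS	INTRON	AAT	3	0	170	200
KRAS-1	KRAS	ONCOGENE	INTRON	CA	2	0	120	150
KRAS-2	KRAS	ONCOGENE	INTRON	AAAG	4	0	200	240
NUP88-1	NUP88	ONCOGENE	INTRON	CA	2	0	140	170
NUP88-3	NUP88	ONCOGENE	INTRON	TG	2	0	100	130
NUP88-5	NUP88	ONCOGENE	NONCODING	GATA	4	0	220	260
BRAF-2	BRAF	ONCOGENE	INTRON	CA	2	0	150	180
BRAF-9	BRAF	ONCOGENE	INTRON	TG	2	0	130	160
BRAF-12	BRAF	ONCOGENE	INTRON	AAAG	4	0	240	280
pinch-1	LIMS1	ONCOGENE	INTRON	CA	2	0	110	140
pinch-5	LIMS1	ONCOGENE	INTRON	CA	2	0	160	190
pinch-8	LIMS1	ONCOGENE	NONCODING	GATA	4	0	210	250
pinch-13	LIMS1	ONCOGENE	INTRON	TG	2	0	180	210
MDM2-1	MDM2	ONCOGENE	UTR3	CA	2	0	120	150
MDM2-2	MDM2	ONCOGENE	UTR3	TG	2	0	190	220
MDM2-4	MDM2	ONCOGENE	INTRON	AAAG	4	0	230	270
MYC-E1	MYC	ONCOGENE	EXON	CAG	3	0	160	180
MYC-2	MYC	ONCOGENE	INTRON	CA	2	0	140	170
TMEM97-1	TMEM97	ONCOGENE	INTRON	CA	2	0	100	130
TMEM97-2	TMEM97	ONCOGENE	INTRON	AAT	3	0	150	180
TMEM97-3	TMEM97	ONCOGENE	NONCODING	GATA	4	0	200	240
MLH1-2	MLH1	MMR	INTRON	CA	2	0	130	160
MLH1-4	MLH1	MMR	INTRON	TG	2	0	170	200
MSH2-5	MSH2	MMR	INTRON	CA	2	0	120	150
MSH2-12	MSH2	MMR	INTRON	TG	2	0	180	210
MSH2-15	MSH2	MMR	INTRON	AAAG	4	0	220	260
MSH6-1	MSH6	MMR	INTRON	CA	2	0	110	140
MSH6-3	MSH6	MMR	INTRON	CAG	3	0	160	190
PMS2-1	PMS2	MMR	INTRON	CA	2	0	140	170
PMS2-3	PMS2	MMR	INTRON	A	1	0	95	120
MGMT-1	MGMT	DNAR	INTRON	CA	2	0	120	150
MGMT-3	MGMT	DNAR	INTRON	TG	2	0	150	180
MGMT-5	MGMT	DNAR	INTRON	CAG	3	0	180	210
MGMT-7	MGMT	DNAR	INTRON	CA	2	0	100	130
MGMT-10	MGMT	DNAR	INTRON	AC	2	0	140	170
MGMT-12	MGMT	DNAR	NONCODING	GT	2	0	200	230
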