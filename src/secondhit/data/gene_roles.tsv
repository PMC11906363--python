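gene_id	role	in_tier1_list	fusion_only	intragenic_del_activatable
ACVR1	oncogene	1	0	0
ASXL1	tsg	1	0	0
ATM	tsg	1	0	0
ATRX	tsg	1	0	0
BCOR	tsg	1	0	0
BRAF	oncogene	1	0	0
CCND2	oncogene	1	0	0
CDK4	oncogene	1	0	0
CDK6	oncogene	1	0	0
CDKN2A	tsg	1	0	0
CDKN2B	tsg	1	0	0
EGFR	oncogene	1	0	0
FGFR1	oncogene	1	0	0
H3F3A	oncogene	1	0	0
HIST1H3B	oncogene	1	0	0
HIST1H3C	oncogene	1	0	0
HIST2H3C	oncogene	1	0	0
ID2	oncogene	1	0	0
KDM6B	tsg	1	0	0
KDR	oncogene	1	0	0
KIT	oncogene	1	0	0
KRAS	oncogene	1	0	0
MET	oncogene	1	0	0
MYC	oncogene	1	0	0
MYCN	oncogene	1	0	0
NF1	tsg	1	0	0
NTRK1	oncogene	1	1	0
NTRK2	oncogene	1	1	0
NTRK3	oncogene	1	1	0
PDGFRA	oncogene	1	0	1
PIK3CA	oncogene	1	0	0
PIK3R1	tsg	1	0	0
PPM1D	oncogene	1	0	0
PTEN	tsg	1	0	0
RB1	tsg	1	0	0
SETD2	tsg	1	0	0
TERT	oncogene	1	0	0
TOP3A	oncogene	1	0	0
TP53	tsg	1	0	0
CREBBP	tsg	0	0	0
MSH6	tsg	0	0	0
WT1	tsg	0	0	0
APC	tsg	0	0	0
FGFR2	oncogene	0	0	0
ERBB2	oncogene	0	0	0
IDH1	oncogene	0	0	0
SMARCB1	tsg	0	0	0
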