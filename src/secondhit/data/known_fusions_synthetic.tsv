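gene_5p	gene_3p	name
KIAA1549	BRAF	KIAA1549-BRAF
ETV6	NTRK3	ETV6-NTRK3
NACC2	NTRK2	NACC2-NTRK2
QKI	NTRK2	QKI-NTRK2
TPM3	NTRK1	TPM3-NTRK1
FGFR1	TACC1	FGFR1-TACC1
FGFR3	TACC3	FGFR3-TACC3
MYB	QKI	MYB-QKI
EML4	ALK	EML4-ALK
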