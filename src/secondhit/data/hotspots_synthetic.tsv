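gene_id	residue	recurrence_count
NF1	489	8
NF1	844	6
NF1	1276	5
NF1	100	2
BRAF	600	9999
KRAS	12	9999
KRAS	13	999
KRAS	61	999
EGFR	858	999
H3F3A	27	999
H3F3A	34	500
IDH1	132	999
PIK3CA	1047	999
PIK3CA	545	999
TP53	175	999
TP53	273	999
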