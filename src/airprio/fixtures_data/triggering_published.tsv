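# Published triggering-analysis summary: asterisk-scale individual probability
# (stars, 1-5) and accumulated coverage score (%) per protein and condition.
gene	uniprot_id	disease	stars	accumulated_score
AKT1	P31749	RA	1	86.96
AKT1	P31749	AA	3	84.55
AKT1	P31749	NA	4	84.18
STAT1	P42224	RA	2	91.3
STAT1	P42224	AA	4	89.27
STAT1	P42224	NA	4	88.27
MAPK13	O15264	RA	2	89.13
MAPK13	O15264	AA	4	89.27
MAPK13	O15264	NA	5	88.27
TLR4	O00206	AA	4	90.12
TLR4	O00206	NA	4	89.28
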