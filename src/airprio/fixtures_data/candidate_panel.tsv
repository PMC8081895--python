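# The 94-protein candidate biomarker panel. 80 symbols are recoverable from the
# published tables and text; the full list was not published, so 14 entries are
# SYNTHETIC placeholders (SYNCAND*) that stand in for the unpublished members.
# uniprot_id = NA where not printed.
uniprot_id	gene_symbol	source
NA	ADAM33	published
NA	ADRB1	published
P31749	AKT1	published
NA	ALOX15	published
P09917	ALOX5	published
NA	APAF1	published
Q07812	BAX	published
NA	C3AR1	published
P51671	CCL11	published
NA	CCL17	published
P13501	CCL5	published
NA	CD40	published
NA	CD48	published
NA	CD86	published
P36222	CHI3L1	published
A8K7I4	CLCA1	published
NA	CTSC	published
NA	CTSG	published
NA	DUSP1	published
NA	EIF5A	published
NA	FOXP3	published
NA	FPR3	published
NA	GPX3	published
NA	HLA-DQB1	published
NA	HLA-DRB1	published
P01579	IFNG	published
P22301	IL10	published
P35225	IL13	published
Q16552	IL17A	published
NA	IL1R1	published
P27930	IL1R2	published
P60568	IL2	published
Q9H293	IL25	published
P14784	IL2RB	published
O95760	IL33	published
P05112	IL4	published
P24394	IL4R	published
P05113	IL5	published
P05231	IL6	published
NA	IL8	published
P15248	IL9	published
NA	IRAK3	published
NA	ITGAL	published
NA	ITGB7	published
NA	ITGB8	published
NA	LGALS3	published
NA	LYN	published
O15264	MAPK13	published
NA	MSR1	published
NA	MUC2	published
P98088	MUC5AC	published
Q9HC84	MUC5B	published
NA	NCF2	published
NA	NFATC1	published
NA	NFKBIZ	published
NA	NLRP3	published
NA	NOS2	published
Q8N138	ORMDL3	published
NA	PHLDA1	published
NA	PI3	published
Q15063	POSTN	published
P43116	PTGER2	published
NA	PTPRC	published
P12724	RNASE3	published
NA	S100A9	published
NA	S1PR5	published
P14151	SELL	published
P05120	SERPINB2	published
NA	SMURF1	published
NA	SOS1	published
NA	SPP1	published
P42224	STAT1	published
NA	SVIL	published
P01137	TGFB1	published
O00206	TLR4	published
P01375	TNF	published
NA	TNFAIP3	published
NA	TSLP	published
NA	VCAN	published
NA	ZAP70	published
NA	SYNCAND01	synthetic
NA	SYNCAND02	synthetic
NA	SYNCAND03	synthetic
NA	SYNCAND04	synthetic
NA	SYNCAND05	synthetic
NA	SYNCAND06	synthetic
NA	SYNCAND07	synthetic
NA	SYNCAND08	synthetic
NA	SYNCAND09	synthetic
NA	SYNCAND10	synthetic
NA	SYNCAND11	synthetic
NA	SYNCAND12	synthetic
NA	SYNCAND13	synthetic
NA	SYNCAND14	synthetic
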