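# Published whole-disease relationship scores (0-100) for every candidate in the
# two top categories per condition, plus TNF/RA which is printed in the
# specificity panel. Candidates absent from a disease column scored below the
# high threshold and their values were not published.
gene	disease	score	source
IL5	RA	92.43	published
IL13	RA	91.82	published
IL10	RA	90.26	published
IL6	RA	90.15	published
IL9	RA	89.85	published
IFNG	RA	88.99	published
IL4	RA	88.49	published
PTGER2	RA	88.16	published
IL2	RA	88.13	published
IL4R	RA	85.21	published
IL2RB	RA	84.15	published
TNF	RA	75.99	published
MUC5AC	AA	88.43	published
ALOX5	AA	87.92	published
CHI3L1	AA	86.53	published
ORMDL3	AA	83.15	published
RNASE3	AA	82.96	published
POSTN	AA	82.79	published
CLCA1	AA	82.78	published
MUC5B	AA	82.64	published
IL4R	AA	81.40	published
IL17A	AA	81.22	published
IL33	AA	81.12	published
SELL	AA	81.04	published
IL25	AA	80.90	published
SERPINB2	AA	80.82	published
IL1R2	AA	79.06	published
BAX	AA	78.36	published
TGFB1	AA	78.21	published
MUC5AC	NA	91.14	published
CHI3L1	NA	89.91	published
POSTN	NA	89.75	published
IL33	NA	89.01	published
RNASE3	NA	88.08	published
SELL	NA	88.01	published
ORMDL3	NA	87.70	published
MUC5B	NA	86.88	published
ALOX5	NA	86.69	published
IL17A	NA	86.69	published
PTGER2	NA	84.79	published
CCL5	NA	83.26	published
IL25	NA	82.81	published
CLCA1	NA	81.62	published
SERPINB2	NA	79.93	published
CCL11	NA	78.30	published
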