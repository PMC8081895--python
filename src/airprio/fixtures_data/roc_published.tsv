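# Published ROC results (control vs respiratory allergy block) for the jointly
# supported biomarkers: group sizes, AUC with 95% CI, and expression threshold.
gene	comparison	n_a	n_b	auc	ci_low	ci_high	threshold
IL1R2	control_vs_RA	27	14	0.82	0.67	0.96	8.91
IL4R	control_vs_RA	27	14	0.79	0.65	0.94	9.9
SELL	control_vs_RA	27	14	0.78	0.63	0.93	9.04
TLR4	control_vs_RA	27	14	0.86	0.75	0.97	9.9
CCL5	control_vs_RA	27	14	0.87	0.75	0.98	6.11
TGFB1	control_vs_RA	28	14	0.77	0.59	0.96	6.92
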