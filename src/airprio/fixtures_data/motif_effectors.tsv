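# Per-motif effector proteins. Transcribed from the published per-motif ranking
# (very-high/high entries, all reported as effectors of their motif) plus the
# published shared-protein motif assignments. Motifs with no published
# high-or-stronger entry (goblet_cell_hyperplasia, innervation_and_hyperexcitability)
# have no rows and are not used for network scoring.
motif_id	protein	reference
acute_response	IL10	published
acute_response	IL4	published
acute_response	IL2	published
acute_response	IL9	published
acute_response	IFNG	published
acute_response	PTGER2	published
acute_response	IL4R	published
acute_response	IL2RB	published
late_phase_response	IL13	published
late_phase_response	IL5	published
late_phase_response	IL6	published
late_phase_response	TNF	published
th2_pulmonary_inflammation	IL10	published
th2_pulmonary_inflammation	IL13	published
th2_pulmonary_inflammation	IL4	published
th2_pulmonary_inflammation	IL5	published
th2_pulmonary_inflammation	CCL17	published
granulocyte_eosinophil_infiltration	IFNG	published
granulocyte_eosinophil_infiltration	IL4R	published
granulocyte_eosinophil_infiltration	CCL11	published
granulocyte_eosinophil_infiltration	TGFB1	published
granulocyte_eosinophil_infiltration	CCL5	published
granulocyte_eosinophil_infiltration	CD40	published
granulocyte_eosinophil_infiltration	RNASE3	published
granulocyte_eosinophil_infiltration	ALOX5	published
granulocyte_eosinophil_infiltration	SELL	published
granulocyte_eosinophil_infiltration	IL17A	published
granulocyte_eosinophil_infiltration	ITGAL	published
granulocyte_eosinophil_infiltration	POSTN	published
granulocyte_eosinophil_infiltration	SERPINB2	published
th17_pulmonary_inflammation	IL17A	published
neutrophil_infiltration	IL6	published
neutrophil_infiltration	LGALS3	published
dendritic_cell_activation	TLR4	published
dendritic_cell_activation	IL33	published
ecm_deposition	ORMDL3	published
angiogenesis_asthma	IL33	published
angiogenesis_asthma	ADAM33	published
angiogenesis_asthma	CHI3L1	published
angiogenesis_asthma	POSTN	published
angiogenesis_asthma	IL25	published
airway_smooth_muscle_hypertrophy_hyperplasia	TNF	published
epithelial_dysfunction	CCL5	published
airway_smooth_muscle_hypercontractibility	IL4R	published
airway_smooth_muscle_hypercontractibility	IL1R2	published
airway_smooth_muscle_hypercontractibility	MUC5AC	published
airway_smooth_muscle_hypercontractibility	CLCA1	published
airway_smooth_muscle_hypercontractibility	MUC5B	published
bronchoconstriction	PTGER2	published
bronchoconstriction	ADRB1	published
mucus_production	IL8	published
mucus_production	IL17A	published
mucus_production	MUC5AC	published
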