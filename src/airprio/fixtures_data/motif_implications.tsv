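# Molecular-motif characterization of respiratory allergy (RA), allergic asthma (AA)
# and non-allergic asthma (NA). Transcribed from the published motif summary matrix:
# strong = strong implication, weak = weaker implication than the other asthma
# variant though still relevant, none = no implication.
motif_id	motif_name	RA	AA	NA
acute_response	Acute Response	strong	strong	none
late_phase_response	Late-Phase Response	strong	strong	none
th2_pulmonary_inflammation	Th2-Mediated Pulmonary Inflammation	none	strong	none
goblet_cell_hyperplasia	Goblet Cell Hyperplasia	none	strong	none
granulocyte_eosinophil_infiltration	Granulocyte (eosinophil) Infiltration	none	strong	weak
th17_pulmonary_inflammation	Th17-Mediated Pulmonary Inflammation	none	weak	strong
neutrophil_infiltration	Neutrophil Infiltration	none	weak	strong
dendritic_cell_activation	Dendritic Cell Activation	none	strong	strong
ecm_deposition	ECM Deposition	none	strong	strong
angiogenesis_asthma	Angiogenesis Asthma	none	strong	strong
airway_smooth_muscle_hypertrophy_hyperplasia	Airway Smooth Muscle Hypertrophy/Hyperplasia	none	strong	strong
epithelial_dysfunction	Epithelial Dysfunction	none	strong	strong
airway_smooth_muscle_hypercontractibility	Airway Smooth Muscle Hypercontractibility	none	strong	strong
innervation_and_hyperexcitability	Innervation And Hyper-Excitability	none	strong	strong
bronchoconstriction	Bronchoconstriction	none	strong	strong
mucus_production	Mucus Production	none	strong	strong
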