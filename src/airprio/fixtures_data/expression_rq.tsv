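# Published relative-quantification (RQ) fold changes of gene expression in the
# disease-specific proteins, each clinical group vs healthy controls, with the
# published multiplicity-adjusted p-values. nd = not determined.
gene	specific_to	comparison	rq	adj_p
IL2RB	RA	RA_vs_control	0.21	3.79E-8
IL2RB	RA	AA_vs_control	0.38	9.24E-8
IL2RB	RA	NA_vs_control	2.68	3.5E-4
TNF	RA	RA_vs_control	0.13	3.5E-10
TNF	RA	AA_vs_control	0.066	3.47E-21
TNF	RA	NA_vs_control	0.41	0.011
PTGER2	RA	RA_vs_control	0.30	7.3E-8
PTGER2	RA	AA_vs_control	0.48	1.36E-6
PTGER2	RA	NA_vs_control	1.86	0.003
IL10	RA	RA_vs_control	0.15	5.06E-6
IL10	RA	AA_vs_control	nd	nd
IL10	RA	NA_vs_control	6.14	1.6E-6
ALOX5	AA	RA_vs_control	0.25	2.8E-5
ALOX5	AA	AA_vs_control	0.23	6.13E-8
ALOX5	AA	NA_vs_control	nd	nd
RNASE3	AA	RA_vs_control	0.41	8.9E-3
RNASE3	AA	AA_vs_control	0.35	6.09E-4
RNASE3	AA	NA_vs_control	nd	nd
TGFB1	AA	RA_vs_control	0.20	3.5E-13
TGFB1	AA	AA_vs_control	0.18	4.7E-20
TGFB1	AA	NA_vs_control	nd	nd
CCL5	AA	RA_vs_control	0.13	2.8E-10
CCL5	AA	AA_vs_control	0.14	3.18E-12
CCL5	AA	NA_vs_control	nd	nd
ITGAL	AA	RA_vs_control	0.39	5.3E-6
ITGAL	AA	AA_vs_control	0.45	2.58E-5
ITGAL	AA	NA_vs_control	nd	nd
CD40	AA	RA_vs_control	0.26	7.2E-5
CD40	AA	AA_vs_control	0.35	3.48E-5
CD40	AA	NA_vs_control	nd	nd
SERPINB2	AA	RA_vs_control	nd	nd
SERPINB2	AA	AA_vs_control	1.67	nd
SERPINB2	AA	NA_vs_control	8.94	7.6E-5
SELL	AA	RA_vs_control	0.14	4.25E-8
SELL	AA	AA_vs_control	0.10	3.2E-15
SELL	AA	NA_vs_control	0.53	0.039
LGALS3	NA	RA_vs_control	0.46	9.9E-4
LGALS3	NA	AA_vs_control	0.46	1.9E-5
LGALS3	NA	NA_vs_control	2.06	0.006
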