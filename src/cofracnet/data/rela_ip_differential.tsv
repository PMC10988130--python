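# RELA co-immunoprecipitation differential abundance example (MCF-7 cells,
# NF-kB inhibited vs uninhibited; bait = anti-RELA, control = nonspecific IgG).
# Curated from a published differential-interactor table whose inclusion rule is
# |log2FC| > 0.58 and q < 0.05 in the between-condition bait comparison.
# Values are as printed (3-decimal / scientific precision), except SMARCAD1's
# q_inh_vs_uninh, printed as 0.050 under the q < 0.05 inclusion rule: it is
# recorded as 0.0499, consistent with both the printed rounding and that rule.
uniprot	gene	log2fc_inh_vs_ctrl	q_inh_vs_ctrl	log2fc_uninh_vs_ctrl	q_uninh_vs_ctrl	log2fc_inh_vs_uninh	q_inh_vs_uninh
P09525	ANXA4	0.13	0.277	1.08	0.028	-1.14	0.027
P81605	DCD	-0.53	0.107	0.77	0.047	-1.03	0.022
Q6UWP8	SBSN	-0.40	0.088	0.70	0.021	-0.90	0.015
P20336	RAB3A	-0.04	0.338	0.75	0.035	-0.68	0.032
Q02809	PLOD1	0.27	0.326	0.65	0.019	-0.67	0.042
Q8NBJ5	COLGALT1	0.36	0.051	0.64	0.019	-0.63	0.028
Q7Z5P9	MUC19	1.06	0.003	0.54	4.22E-04	0.59	0.023
Q9NZM1	MYOF	0.55	0.104	0.71	0.001	0.60	0.034
P25963	NFKBIA	4.00	5.96E-09	4.13	4.48E-08	0.61	0.015
Q8IWE2	FAM114A1	0.79	0.021	0.16	0.143	0.64	0.045
Q13510	ASAH1	0.56	0.044	1.02	7.30E-06	0.66	0.001
Q9NZD8	SPG21	0.40	0.178	0.62	0.010	0.66	0.024
P51809	VAMP7	0.47	0.216	1.06	0.002	0.69	0.021
P49257	LMAN1	1.05	0.045	0.45	0.016	0.69	0.021
O14867	BACH1	0.77	0.008	0.47	0.026	0.70	0.020
O00625	PIR	0.57	0.066	0.87	2.00E-06	0.70	0.028
P62834	RAP1A	0.60	0.010	0.87	1.91E-07	0.70	0.007
O00264	PGRMC1	0.87	0.032	1.43	1.66E-04	0.72	0.029
P50542	PEX5	0.94	0.023	0.47	0.009	0.73	0.034
Q9H4L7	SMARCAD1	1.55	0.003	-0.39	0.179	0.74	0.0499
P35611	ADD1	0.65	0.011	0.42	0.002	0.75	0.016
Q9UNX3	RPL26L1	0.23	0.406	1.02	6.47E-07	0.79	0.009
Q15653	NFKBIB	3.68	9.80E-07	2.89	2.68E-06	0.84	0.028
Q6NXT1	ANKRD54	0.71	0.003	0.50	9.91E-06	0.84	0.002
Q9Y3B4	SF3B6	0.55	0.096	1.08	0.001	0.86	0.035
Q9UKD2	MRTO4	1.33	0.004	0.94	3.71E-04	0.86	0.020
L0R8F8	MIEF1	0.56	0.102	0.79	5.61E-05	0.88	0.005
Q8NF37	LPCAT1	0.26	0.343	0.77	0.047	1.05	0.046
Q99685	MGLL	0.87	0.024	0.31	0.257	1.09	0.002
Q9UBM7	DHCR7	2.97	4.19E-04	2.13	2.28E-05	1.15	0.025
Q13191	CBLB	0.91	0.007	-0.27	0.005	1.26	1.41E-05
Q16254	E2F4	0.77	0.027	0.41	0.318	1.30	0.001
O95562	SFT2D2	1.69	0.026	1.52	0.007	1.34	0.032
P20674	COX5A	0.73	0.043	0.32	0.001	1.50	0.004
B3EWG3	FAM25A	1.16	0.030	0.46	4.57E-04	1.57	0.014
Q16563	SYPL1	0.46	0.366	1.43	6.30E-05	1.68	0.017
P62736	ACTA2	1.75	0.025	-0.05	0.358	2.80	0.003
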