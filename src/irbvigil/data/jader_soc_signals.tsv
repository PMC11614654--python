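soc	soc_code	n	ror	ror_lo95	ror_hi95	prr	chi2	ebgm	ebgm05	ic	ic025
Metabolism and nutrition disorders	10065941	94	5.17	4.14	6.46	4.45	260.87	4.44	3.55	2.15	0.48
Cardiac disorders	10077162	61	2.22	1.7	2.89	2.08	36.05	2.08	1.59	1.05	-0.62
Investigations	10063264	58	1.11	0.85	1.46	1.1	0.6	1.1	0.84	0.14	-1.53
Renal and urinary disorders	10073515	57	2.69	2.05	3.54	2.51	54.14	2.51	1.91	1.33	-0.34
Nervous system disorders	10000346	36	0.79	0.56	1.1	0.8	1.95	0.8	0.57	-0.32	-1.99
Immune system disorders	10000206	32	0.82	0.58	1.18	0.83	1.13	0.83	0.58	-0.26	-1.93
Hepatobiliary disorders	10071634	31	1.35	0.94	1.94	1.33	2.67	1.33	0.93	0.41	-1.26
Musculoskeletal and connective tissue disorders	10074599	30	2.09	1.45	3.03	2.03	16.18	2.03	1.41	1.02	-0.65
Gastrointestinal disorders	10000050	28	0.64	0.44	0.94	0.66	5.36	0.66	0.45	-0.6	-2.27
General disorders and administration site conditions	10017581	22	0.54	0.35	0.83	0.56	8.28	0.56	0.36	-0.84	-2.51
Vascular disorders	10000358	19	0.45	0.29	0.72	0.47	11.99	0.47	0.3	-1.08	-2.75
Skin and subcutaneous tissue disorders	10058820	17	0.78	0.48	1.26	0.79	1.03	0.79	0.49	-0.35	-2.02
Blood and lymphatic system disorders	10073485	11	0.3	0.17	0.55	0.32	17.5	0.32	0.17	-1.67	-3.34
Respiratory, thoracic and mediastinal disorders	10051545	9	0.27	0.14	0.52	0.28	17.37	0.28	0.15	-1.82	-3.49
Injury, poisoning and procedural complications	10000044	9	0.88	0.45	1.69	0.88	0.16	0.88	0.45	-0.19	-1.86
Endocrine disorders	10080230	8	0.71	0.35	1.43	0.72	0.91	0.72	0.36	-0.48	-2.15
Psychiatric disorders	10082331	5	0.41	0.17	0.99	0.42	4.21	0.42	0.17	-1.27	-2.94
Infections and infestations	10060921	4	0.16	0.06	0.42	0.16	17.87	0.16	0.06	-2.61	-4.28
Neoplasms benign, malignant and unspecified (incl cysts and polyps)	10068532	3	0.38	0.12	1.18	0.38	3.05	0.38	0.12	-1.39	-3.06
Surgical and medical procedures	10059486	3	1.5	0.48	4.65	1.49	0.49	1.49	0.48	0.58	-1.09
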