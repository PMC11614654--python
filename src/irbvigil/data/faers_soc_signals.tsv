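soc	soc_code	n	ror	ror_lo95	ror_hi95	prr	chi2	ebgm	ebgm05	ic	ic025
General disorders and administration site conditions	10017581	2186	0.64	0.61	0.67	0.68	396.08	0.68	0.65	-0.55	-2.22
Nervous system disorders	10000346	1881	1.22	1.17	1.28	1.2	68.48	1.2	1.14	0.26	-1.4
Gastrointestinal disorders	10000050	1559	0.99	0.94	1.04	0.99	0.1	0.99	0.94	-0.01	-1.68
Investigations	10063264	1424	1.27	1.2	1.34	1.25	73.82	1.25	1.18	0.32	-1.35
Metabolism and nutrition disorders	10065941	1229	3.23	3.04	3.42	3.08	1760.26	3.08	2.9	1.62	-0.05
Injury, poisoning and procedural complications	10000044	1216	0.62	0.59	0.66	0.65	263.25	0.65	0.61	-0.63	-2.3
Renal and urinary disorders	10073515	1124	3.33	3.13	3.53	3.19	1716.22	3.18	3	1.67	0.01
Skin and subcutaneous tissue disorders	10058820	1031	1.04	0.98	1.11	1.04	1.87	1.04	0.98	0.06	-1.61
Respiratory, thoracic and mediastinal disorders	10051545	986	1.14	1.07	1.22	1.14	16.75	1.14	1.06	0.18	-1.48
Vascular disorders	10000358	967	2.53	2.37	2.7	2.45	848.18	2.45	2.3	1.29	-0.37
Cardiac disorders	10077162	797	1.67	1.56	1.8	1.64	206.26	1.64	1.53	0.72	-0.95
Musculoskeletal and connective tissue disorders	10074599	768	0.78	0.73	0.84	0.79	43.41	0.79	0.74	-0.33	-2
Psychiatric disorders	10082331	702	0.66	0.61	0.71	0.67	119.23	0.67	0.62	-0.57	-2.24
Infections and infestations	10060921	400	0.4	0.36	0.44	0.41	354.73	0.41	0.37	-1.28	-2.95
Blood and lymphatic system disorders	10073485	314	1.01	0.9	1.13	1.01	0.04	1.01	0.9	0.02	-1.65
Neoplasms benign, malignant and unspecified (incl cysts and polyps)	10068532	302	0.61	0.55	0.69	0.62	73.31	0.62	0.55	-0.69	-2.36
Eye disorders	10000173	285	0.78	0.69	0.88	0.78	17.23	0.78	0.7	-0.35	-2.02
Hepatobiliary disorders	10071634	272	1.63	1.45	1.84	1.62	65.18	1.62	1.44	0.7	-0.97
Product issues	10078577	254	0.87	0.77	0.99	0.87	4.73	0.87	0.77	-0.2	-1.86
Immune system disorders	10000206	172	0.85	0.73	0.98	0.85	4.79	0.85	0.73	-0.24	-1.91
Ear and labyrinth disorders	10063559	123	1.53	1.28	1.83	1.53	22.65	1.53	1.28	0.61	-1.05
Surgical and medical procedures	10059486	89	0.36	0.29	0.45	0.37	99.45	0.37	0.3	-1.45	-3.12
Pregnancy, puerperium and perinatal conditions	10084854	83	1.05	0.84	1.3	1.05	0.16	1.05	0.84	0.06	-1.6
Endocrine disorders	10080230	76	1.62	1.3	2.03	1.62	18.11	1.62	1.29	0.7	-0.97
Reproductive system and breast disorders	10087591	70	0.42	0.34	0.54	0.43	54.58	0.43	0.34	-1.23	-2.9
Congenital, familial and genetic disorders	10000002	66	1.14	0.89	1.45	1.14	1.11	1.14	0.89	0.19	-1.48
Social circumstances	10000209	55	0.64	0.49	0.83	0.64	11.07	0.64	0.49	-0.64	-2.31
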