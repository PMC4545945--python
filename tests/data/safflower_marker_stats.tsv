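locus	repeat_unit	n_units	Na	He	Ho	PIC
NGSaf_2	TC	8	2	0.2580	0.0434	0.2247
NGSaf_9	ACA	7	2	0.4848	0.0434	0.3673
NGSaf_12	CGG	7	2	0.3402	0.0000	0.2823
NGSaf_13	AGC	7	2	0.0831	0.0000	0.0797
NGSaf_14	CAT	7	2	0.1219	0.0434	0.1144
NGSaf_15	TGT	7	2	0.3147	0.0434	0.2652
NGSaf_20	CATT	5	2	0.4990	0.0000	0.3745
NGSaf_22	AG	9	3	0.2344	0.0000	0.2200
NGSaf_23	AC	9	2	0.3856	0.0000	0.3112
NGSaf_28	ATC	7	2	0.0831	0.0000	0.0797
NGSaf_34	CAG	7	3	0.5950	0.0000	0.5261
NGSaf_39	GATG	5	3	0.3553	0.0000	0.3159
NGSaf_43	CT	9	2	0.0425	0.0434	0.0416
NGSaf_44	AGG	7	2	0.4653	0.0000	0.3570
NGSaf_45	GCT	6	2	0.2268	0.0000	0.2011
NGSaf_48	CTT	6	3	0.4990	0.0000	0.4337
NGSaf_49	CAT	6	3	0.5368	0.0000	0.4322
NGSaf_56	GAT	6	2	0.1587	0.0000	0.1461
NGSaf_63	GAA	6	2	0.3147	0.0434	0.2652
NGSaf_65	CTC	6	2	0.2580	0.0434	0.2247
NGSaf_67	AGG	6	2	0.3147	0.0434	0.2652
NGSaf_69	TAC	6	3	0.6353	0.0454	0.5602
NGSaf_73	GTT	6	2	0.1587	0.0869	0.1461
NGSaf_83	AGA	6	2	0.4914	0.0000	0.3707
NGSaf_84	TCA	6	2	0.3147	0.1304	0.2652
NGSaf_89	TCT	6	2	0.4536	0.0000	0.3507
NGSaf_91	TAT	6	2	0.0425	0.0434	0.0416
NGSaf_92	TAC	6	2	0.2268	0.0000	0.2011
NGSaf_94	TCC	6	2	0.4054	0.0434	0.3232
NGSaf_98	TAC	6	2	0.4834	0.0000	0.3665
NGSaf_101	TAT	6	3	0.4158	0.0000	0.3741
NGSaf_105	TGG	6	2	0.3856	0.0000	0.3112
NGSaf_111	CAA	6	2	0.4914	0.0000	0.3707
NGSaf_114	AAT	6	2	0.1587	0.0000	0.1461
NGSaf_115	CTG	6	2	0.0425	0.0434	0.0416
NGSaf_117	GAA	6	2	0.0831	0.0000	0.0797
NGSaf_130	TGG	6	2	0.4234	0.0000	0.3337
NGSaf_138	TGT	6	2	0.0831	0.0000	0.0797
NGSaf_142	TGT	6	3	0.4473	0.0454	0.3655
NGSaf_145	GGA	6	2	0.4990	0.0000	0.3745
NGSaf_148	CAT	6	2	0.4536	0.0000	0.3507
NGSaf_151	GAT	6	2	0.4914	0.0000	0.3707
NGSaf_152	CAA	6	3	0.4682	0.0952	0.4149
NGSaf_154	GAT	6	4	0.5826	0.0000	0.4938
NGSaf_155	AAG	6	2	0.3367	0.0000	0.2800
NGSaf_156	CAC	6	3	0.2637	0.0434	0.2385
NGSaf_158	TAA	6	2	0.1219	0.0434	0.1144
NGSaf_164	TGT	6	2	0.2268	0.0000	0.2011
NGSaf_173	AGC	6	2	0.4536	0.0000	0.3507
NGSaf_178	ATC	6	2	0.4763	0.0000	0.3629
NGSaf_181	GTA	6	3	0.3279	0.0434	0.2954
NGSaf_201	TAT	6	2	0.4914	0.0869	0.3707
NGSaf_204	AAC	6	2	0.3856	0.0000	0.3112
NGSaf_210	TCT	6	2	0.4977	0.0000	0.3738
NGSaf_211	GAT	6	2	0.4958	0.0909	0.3729
NGSaf_236	ATC	6	2	0.4921	0.0000	0.3710
NGSaf_237	ATT	6	2	0.4962	0.9130	0.3731
NGSaf_238	CAT	6	2	0.4395	0.0434	0.3429
NGSaf_239	ATT	6	2	0.2777	0.2380	0.2391
NGSaf_242	AAG	6	2	0.1937	0.0434	0.1749
NGSaf_245	ATG	6	2	0.4938	0.0000	0.3718
NGSaf_248	TCT	6	2	0.0831	0.0000	0.0797
NGSaf_255	TCA	6	2	0.4848	0.0434	0.3673
NGSaf_257	ACA	6	2	0.3856	0.0000	0.3112
NGSaf_259	ATT	6	2	0.4763	0.0000	0.3629
NGSaf_261	TTC	6	2	0.4990	0.0869	0.3745
NGSaf_262	TAT	6	3	0.5207	0.0434	0.4059
NGSaf_264	TTA	6	3	0.5051	0.0454	0.4511
NGSaf_265	AAT	6	2	0.2508	0.0588	0.2193
NGSaf_266	TGA	6	3	0.1975	0.0434	0.1847
NGSaf_273	GAA	6	2	0.4914	0.0000	0.3707
NGSaf_276	AGA	6	2	0.0867	0.0000	0.0830
NGSaf_279	AAG	6	2	0.3254	0.0454	0.2724
NGSaf_281	AG	22	3	0.6258	0.0000	0.5509
NGSaf_282	AG	18	3	0.4050	0.0000	0.3679
NGSaf_286	GA	16	3	0.6124	0.0000	0.5432
NGSaf_289	AT	16	3	0.6200	0.9565	0.5435
NGSaf_292	CT	16	2	0.3856	0.0000	0.3112
NGSaf_294	CA	15	3	0.3494	0.0714	0.3084
NGSaf_295	CT	15	2	0.4716	0.0000	0.3604
NGSaf_296	TC	15	2	0.4536	0.0000	0.3507
NGSaf_300	CA	13	3	0.5141	0.0000	0.4608
NGSaf_301	CA	12	2	0.4567	0.0000	0.3524
NGSaf_306	CT	14	2	0.1244	0.0000	0.1167
NGSaf_307	CT	14	2	0.3046	0.0000	0.2582
NGSaf_308	CT	13	2	0.4990	0.0000	0.3745
NGSaf_309	GA	18	3	0.4390	0.0454	0.3746
NGSaf_310	GA	16	2	0.4958	0.0000	0.3729
NGSaf_313	GT	13	3	0.4297	0.0000	0.3854
NGSaf_314	GT	12	3	0.4917	0.0000	0.4076
NGSaf_322	TC	15	2	0.5000	0.0000	0.3750
NGSaf_323	TC	13	2	0.4501	0.6842	0.3488
NGSaf_324	TG	15	4	0.6228	0.0434	0.5457
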