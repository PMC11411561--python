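name	sample	character	device	depth	latitude	longitude	delta_he3	delta_ntu	potential_temperature	salinity
Iri_Site1_p	490CTD_b1	Plume	CTD tow-yo	2616	13.35	-44.90	28.3	0.053	2.73	34.94
Iri_Site1_bp	490CTD_b13	Below plume	CTD tow-yo	3282	13.35	-44.90	5.3	0.021	2.38	34.92
Iri_Site2_rp	502CTD_b3	Rising plume	CTD vertical	2477	13.33	-44.91	–	0.49	2.85	34.93
Iri_Site2_p	502CTD_b5	Plume	CTD vertical	2653	13.33	-44.91	76.7	0.117	2.72	34.93
Iri_Site2_ap	502CTD_b19	Above plume	CTD vertical	2568	13.33	-44.91	–	0.011	2.89	34.95
Iri_Site3_p1	513CTD_b7	Plume	CTD tow-yo	2600	13.32	-44.91	22.3	0.045	2.75	34.94
Iri_Site3_p2	513CTD_b10	Plume	CTD tow-yo	2570	13.34	-44.91	15.8	0.034	2.68	34.93
Ash_Site1_f	554ROV_2	Fluid	ROV	3277	12.99	-44.91	–	–	–	–
Ash_Site2_rp1	505CTD_b5	Rising plume I	CTD vertical	3240	12.99	-44.91	127.8	0.132	2.47	34.91
Ash_Site2_rp2	505CTD_b12	Rising plume II	CTD vertical	3110	12.99	-44.91	36.6	0.061	2.47	34.92
Ash_Site2_p	505CTD_b17	Above plume	CTD vertical	2900	12.99	-44.91	–	0.016	2.52	34.93
Ash_Site3_rp	519CTD_b11	Rising plume	CTD vertical	3947	12.97	-44.86	183.1	0.268	2.04	34.88
Ash_Site3_p	519CTD_b16	Plume	CTD vertical	3815	12.97	-44.86	14.2	0.058	2.01	34.89
Sem_Site1_f	508ROV_4	Fluid	ROV	2446	13.51	-44.96	–	–	–	–
Sem_Site2_bg	529CTD_b7	Backgr.	CTD vertical	1880	13.52	-44.96	–	0.01	3.7	35.0
Sem_Site3_bg	530CTD_b2	Backgr.	CTD tow-yo	2289	13.52	-44.96	5.2	0.011	2.9	35.0
Sem_Site4_df	524CTD_b1	Above mussel field	CTD vertical	2427	13.51	-44.96	266.1	0.027	3.2	34.9
LHF_Site1_bp	547CTD_b13	Below plume	CTD vertical	2495	14.75	-44.98	11.3	0.014	2.77	34.94
LHF_Site1_p	547CTD_b4	Plume	CTD vertical	2727	14.75	-44.98	32.2	0.016	2.59	34.93
LHF_Site2_df	544ROV_4	5 cm above mussel bed	ROV	3037	14.75	-44.98	–	–	–	–
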