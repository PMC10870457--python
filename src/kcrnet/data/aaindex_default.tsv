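index_id	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y	X
ABODERIN_MOBILITY	5.1	0.0	0.7	1.8	9.6	4.1	1.6	9.3	1.3	10.0	8.7	0.6	4.9	1.4	2.0	3.1	3.5	8.5	9.2	8.0	0.0
ARGOS_MEMBRANE_BURIED	0.61	1.07	0.46	0.47	2.02	0.07	0.61	2.22	1.15	1.53	1.18	0.06	1.95	0.0	0.6	0.05	0.05	1.32	2.65	1.88	0.0
ABRAHAM_LEO_HYDROPHOBICITY	0.44	0.58	-0.31	-0.34	2.54	0.0	-0.01	2.46	-2.45	2.46	1.1	-1.32	1.29	-0.71	-2.42	-0.84	-0.41	1.73	2.56	1.63	0.0
BULL_BREESE_SURFACE_TENSION	0.61	0.36	0.61	0.51	-1.52	0.81	0.69	-1.45	0.46	-1.65	-0.66	0.89	-0.17	0.97	0.69	0.42	0.29	-0.75	-1.2	-1.43	0.0
BLACK_MOULD_HYDROPHOBICITY	0.616	0.68	0.028	0.043	1.0	0.501	0.165	0.943	0.283	0.943	0.738	0.236	0.711	0.251	0.0	0.359	0.45	0.825	0.878	0.88	0.0
CID_STRUCTURE_HYDROPHOBICITY	0.02	0.77	-1.04	-1.14	1.35	-0.8	0.26	1.81	-0.41	1.14	1.0	-0.77	-0.09	-1.1	-0.42	-0.97	-0.77	1.13	1.71	1.11	0.0
CASARI_SIPPL_ENERGY	0.2	1.9	-1.4	-1.3	1.0	-0.1	0.4	1.4	-1.6	0.5	0.5	-0.5	-1.0	-1.1	-0.7	-0.7	-0.4	0.7	1.6	0.5	0.0
ENGELMAN_GES_TRANSFER	-1.6	-2.0	9.2	8.2	-3.7	-1.0	3.0	-3.1	8.8	-2.8	-3.4	4.8	0.2	4.1	12.3	-0.6	-1.2	-2.6	-1.9	0.7	0.0
EISENBERG_CONSENSUS	0.815	0.394	1.283	1.445	0.695	0.714	1.18	0.603	1.545	0.603	0.714	1.296	1.236	1.348	1.475	1.115	1.184	0.606	0.808	1.089	0.0
COWAN_RPHPLC_PH34	0.62	0.29	-0.9	-0.74	1.19	0.48	-0.4	1.38	-1.5	1.06	0.64	-0.78	0.12	-0.85	-2.53	-0.18	-0.05	1.08	0.81	0.26	0.0
COWAN_RPHPLC_PH75	0.31	1.54	-0.77	-0.64	1.79	0.0	0.13	1.8	-0.99	1.7	1.23	-0.6	0.72	-0.22	-1.01	-0.04	0.26	1.22	2.25	0.96	0.0
FASMAN_HYDROPHOBICITY	-0.21	-6.04	1.36	2.3	-4.65	0.0	-1.23	-4.81	3.88	-4.68	-3.66	0.96	0.75	1.52	2.11	1.74	0.78	-3.5	-3.32	-1.01	0.0
GUY_TRANSFER_ENERGY	0.75	1.0	0.0	0.0	2.65	0.0	0.0	2.95	1.5	2.4	1.3	0.69	2.6	0.59	0.75	0.0	0.45	1.7	3.0	2.85	0.0
GOLDSACK_CHALIFOUX	0.1	-1.42	0.78	0.83	-2.12	0.33	-0.5	-1.13	1.4	-1.18	-1.59	0.48	0.73	0.95	1.91	0.52	0.07	-1.27	-0.51	-0.21	0.0
HOPP_WOODS_HYDROPHILICITY	-0.5	-1.0	3.0	3.0	-2.5	0.0	-0.5	-1.8	3.0	-1.8	-1.3	0.2	0.0	0.2	3.0	0.3	-0.4	-1.5	-3.4	-2.3	0.0
JANIN_BURIED_FRACTION	0.28	0.97	-0.52	-1.01	0.46	0.43	-0.31	0.6	-1.62	0.6	0.43	-0.55	-0.42	-0.69	-1.14	-0.19	-0.32	0.6	0.29	-0.15	0.0
JONES_HYDROPHOBICITY	0.87	1.52	0.66	0.67	2.87	0.1	0.87	3.15	1.64	2.17	1.67	0.09	2.77	0.0	0.85	0.07	0.07	1.87	3.77	2.67	0.0
JURETIC_MODIFIED_KD	1.1	2.5	-3.6	-3.2	2.8	-0.64	-3.2	4.5	-4.11	3.8	1.9	-3.5	-1.9	-3.68	-5.1	-0.5	-0.7	4.2	-0.46	-1.3	0.0
KYTE_DOOLITTLE_HYDROPATHY	1.8	2.5	-3.5	-3.5	2.8	-0.4	-3.2	4.5	-3.9	3.8	1.9	-3.5	-1.6	-3.5	-4.5	-0.8	-0.7	4.2	-0.9	-1.3	0.0
KIDERA_FACTOR	-0.27	-1.05	0.81	1.17	-1.43	-0.16	0.28	-0.77	1.7	-1.1	-0.73	0.81	-0.75	1.1	1.87	0.42	0.63	-0.4	-1.57	-0.56	0.0
MIYAZAWA_CONTACT_ENERGY	5.33	7.93	3.59	3.65	9.03	4.48	5.1	8.83	2.95	8.47	8.95	3.71	3.87	3.87	4.18	4.09	4.49	7.63	7.66	5.89	0.0
PARKER_HPLC_HYDROPHILICITY	2.1	1.4	10.0	7.8	-9.2	5.7	2.1	-8.0	5.7	-9.2	-4.2	7.0	2.1	6.0	4.2	6.5	5.2	-3.7	-10.0	-1.9	0.0
PONNUSWAMY_SURROUNDING_HYDROPHOBICITY	0.85	2.1	-1.1	-0.79	1.69	0.0	0.22	3.14	-1.19	1.99	1.42	-0.48	-1.14	-0.42	0.2	-0.52	-0.08	2.53	1.76	1.37	0.0
ROSEMAN_TRANSFER_ENERGY	0.39	0.25	-3.81	-2.91	2.27	0.0	-0.64	1.82	-2.77	1.82	0.96	-1.91	0.99	-1.3	-3.95	-1.24	-1.0	1.3	2.13	1.47	0.0
ROSE_MEAN_FRACTIONAL_AREA	0.74	0.91	0.62	0.62	0.88	0.72	0.78	0.88	0.52	0.85	0.85	0.63	0.64	0.62	0.64	0.66	0.7	0.86	0.85	0.76	0.0
SWEET_EISENBERG_OMH	-0.4	0.17	-1.31	-1.22	1.92	-0.67	-0.64	1.25	-0.67	1.22	1.02	-0.92	-0.49	-0.91	-0.59	-0.55	-0.28	0.91	0.5	1.67	0.0
TANFORD_HYDROPHOBICITY	0.62	0.29	-0.09	-0.74	1.19	0.48	-0.4	1.38	-1.5	1.53	0.64	-0.78	0.12	-0.85	-2.53	-0.18	-0.05	1.8	0.81	0.26	0.0
WILSON_RPHPLC_RETENTION	-0.3	6.3	-1.4	0.0	7.5	1.2	-1.3	4.3	-3.6	6.6	2.5	-0.2	2.2	-0.2	-1.1	-0.6	-2.2	5.9	7.9	7.1	0.0
ZIMMERMAN_POLARITY	0.83	1.48	0.64	0.65	2.75	0.1	1.1	3.07	1.6	2.52	1.4	0.09	2.7	0.0	0.83	0.14	0.54	1.79	0.31	2.97	0.0
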