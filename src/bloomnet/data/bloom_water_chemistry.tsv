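sample_id	T	DO	pH	Tur	SP	NO3_N	NO2_N	NH4_N	TN	PO4_P	COD	Bac	Algae
AD1-1	18.6	11	9.68	29	36	0.43	0.059	0.231	2.27	<0.01	34.7	202.95	73.72
AD1-2	18.7	10.9	9.6	28	39	0.46	0.06	0.241	2.85	<0.01	29.30	241.31	62.34
AD1-3	18.9	10.9	9.71	33	39	0.42	0.058	0.207	3.16	<0.01	26.6	325.40	56.49
AD2-1	19.1	11.1	10.03	62	69	0.11	0.01	0.393	4.22	<0.01	27.0	281.66	57.39
AD2-2	19.1	10.7	10.14	53	65	0.13	0.008	0.351	3.46	<0.01	17.0	192.57	36.17
AD2-3	18.9	10.9	10.17	62	72	0.12	0.009	0.394	4.23	<0.01	21.7	188.57	46.17
AD3-1	18.1	11.3	9.84	44	51	0.1	0.029	0.27	2.78	<0.01	4.4	75.75	9.36
AD3-2	18.3	11.1	9.92	45	49	0.1	0.029	0.202	1.99	0.014	16.7	22.49	35.53
AD3-3	18.5	11.1	9.92	52	53	0.11	0.028	0.299	3.86	<0.01	50.3	17.78	106.9
AD4-1	19.9	9	10.1	30	34	0.05	<0.003	0.134	1.36	<0.01	4.3	27.29	9.20
AD4-2	19.1	9.4	10.19	39	39	0.04	<0.003	0.226	2.03	0.011	17.3	6.79	36.70
AD4-3	18.9	9.5	10.19	40	40	0.06	<0.003	0.247	2.83	<0.01	3.7	11.25	7.77
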