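snp	pos	ld_r2_eur	risk_allele	other_allele	disc_or	disc_lo	disc_hi	disc_p	disc_p_cond	p_het	i2	rep_or	rep_lo	rep_hi	rep_p	rep_p_cond	comb_or	comb_lo	comb_hi	comb_p	comb_p_cond
rs78545330	21995941	0.77	A	T	1.58	1.34	1.86	6.04e-8	1.06e-6	0.480	0	1.57	1.31	1.89	1.19e-6	1.84e-5	1.58	1.39	1.78	3.44e-13	8.37e-11
rs2811712	21998035	0.69	G	A	1.43	1.22	1.68	8.91e-6	1.09e-4	0.202	37.5	1.52	1.34	1.69	3.89e-6	7.60e-5	1.47	1.31	1.65	1.66e-10	3.40e-8
rs3218018	21998139	0.79	G	T	1.59	1.34	1.88	9.39e-8	1.42e-6	0.548	0	1.58	1.31	1.91	1.74e-6	4.76e-5	1.59	1.40	1.80	7.68e-13	2.85e-10
rs3218007	21999800	0.77	T	C	1.57	1.33	1.84	9.04e-8	1.49e-6	0.498	0	1.57	1.31	1.88	1.37e-6	2.23e-5	1.57	1.39	1.77	5.86e-13	1.42e-10
rs3218005	22000247	0.77	C	T	1.57	1.33	1.84	9.05e-8	1.50e-6	0.498	0	1.57	1.31	1.88	1.37e-6	2.23e-5	1.57	1.39	1.77	5.87e-13	1.42e-10
rs3218002	22000841	0.77	A	G	1.57	1.33	1.85	8.65e-8	1.45e-6	0.491	0	1.57	1.31	1.88	1.37e-6	2.23e-5	1.57	1.39	1.77	5.62e-13	1.38e-10
rs2069426	22006273	0.79	T	G	1.59	1.34	1.88	9.47e-8	1.42e-6	0.545	0	1.58	1.31	1.90	2.23e-6	5.85e-5	1.58	1.39	1.80	9.93e-13	3.52e-10
rs974336	22006348	0.77	T	C	1.57	1.33	1.85	7.67e-8	1.25e-6	0.514	0	1.60	1.33	1.92	4.18e-7	7.52e-6	1.58	1.40	1.79	1.58e-13	4.17e-11
rs2069422	22008026	0.70	G	T	1.44	1.22	1.69	1.33e-5	1.45e-4	0.240	30.0	1.52	1.33	1.70	6.53e-6	1.91e-4	1.47	1.30	1.66	4.02e-10	1.05e-7
rs77920300	22012441	0.79	T	C	1.60	1.35	1.89	4.26e-8	6.50e-7	0.583	0	1.57	1.30	1.89	2.43e-6	6.26e-5	1.59	1.40	1.80	4.95e-13	1.78e-10
rs116729641	22025432	0.79	A	G	1.61	1.36	1.90	2.84e-8	4.49e-7	0.614	0	1.57	1.30	1.89	2.31e-6	5.83e-5	1.59	1.40	1.80	3.16e-13	1.17e-10
rs77284052	22025885	0.79	T	C	1.61	1.36	1.90	2.82e-8	4.46e-7	0.618	0	1.57	1.30	1.89	2.31e-6	5.83e-5	1.59	1.40	1.80	3.14e-13	1.16e-10
rs598664	22027551	0.70	C	T	1.46	1.25	1.72	3.46e-6	4.19e-5	0.287	19.9	1.51	1.26	1.81	7.91e-6	2.21e-4	1.48	1.32	1.67	1.21e-10	3.47e-8
rs662463	22030438	0.70	A	G	1.46	1.24	1.71	3.71e-6	4.43e-5	0.288	19.7	1.50	1.25	1.79	1.16e-5	3.03e-4	1.48	1.31	1.66	1.87e-10	4.97e-8
rs79985856	22033824	0.79	T	C	1.61	1.37	1.91	2.03e-8	3.29e-7	0.657	0	1.56	1.30	1.89	2.86e-6	7.22e-5	1.59	1.41	1.80	2.84e-13	1.08e-10
rs79182326	22034267	0.69	T	C	1.45	1.24	1.70	4.30e-6	5.47e-5	0.303	16.3	1.45	1.21	1.73	4.72e-5	1.00e-3	1.45	1.29	1.63	8.33e-10	1.96e-7
rs76213463	22040839	0.79	A	G	1.62	1.37	1.91	1.68e-8	2.76e-7	0.636	0	1.56	1.29	1.88	3.70e-6	8.62e-5	1.59	1.40	1.80	3.08e-13	1.11e-10
rs80166549	22041155	0.79	G	A	1.62	1.37	1.91	1.67e-8	2.74e-7	0.635	0	1.56	1.29	1.88	3.70e-6	8.62e-5	1.59	1.40	1.80	3.06e-13	1.10e-10
rs1333035	22044059	0.69	G	A	1.46	1.25	1.71	1.78e-6	2.50e-5	0.238	30.2	1.50	1.26	1.78	6.87e-6	1.42e-4	1.48	1.31	1.66	5.45e-11	1.36e-8
rs1333034	22044122	0.70	C	T	1.47	1.25	1.72	2.93e-6	3.58e-5	0.307	15.3	1.50	1.26	1.80	9.04e-6	2.34e-4	1.48	1.32	1.67	1.17e-10	3.14e-8
rs17694555	22051295	0.78	G	A	1.61	1.35	1.92	1.61e-7	2.24e-6	0.458	0	1.59	1.40	1.78	1.85e-6	4.28e-5	1.60	1.41	1.82	1.40e-12	4.08e-10
rs17756311	22053895	0.77	A	G	1.63	1.37	1.94	3.95e-8	7.00e-7	0.531	0	1.57	1.30	1.90	2.92e-6	5.74e-5	1.60	1.41	1.82	5.66e-13	1.81e-10
rs74655961	22054164	0.77	G	A	1.64	1.38	1.95	2.90e-8	5.16e-7	0.557	0	1.55	1.28	1.87	5.85e-6	1.11e-4	1.60	1.40	1.82	8.63e-13	2.71e-10
rs17694572	22054356	0.77	A	G	1.63	1.37	1.94	2.89e-8	4.98e-7	0.526	0	1.54	1.28	1.87	6.87e-6	1.28e-4	1.59	1.40	1.81	1.01e-12	3.02e-10
rs77728904	22057530	.	C	A	1.71	1.42	2.05	1.02e-8	1.25e-7	0.687	0	1.74	1.42	2.12	6.28e-8	1.59e-6	1.72	1.50	1.97	3.32e-15	9.34e-13
rs115574830	22059061	0.87	A	T	1.61	1.35	1.92	7.09e-8	8.60e-7	0.574	0	1.55	1.28	1.88	8.34e-6	1.38e-4	1.58	1.39	1.80	2.83e-12	5.32e-10
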