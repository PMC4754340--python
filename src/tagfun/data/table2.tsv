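snp	pos	r2_eur	r2_mxl	r2_asw	ha_or	ha_lo	ha_hi	ha_p	ha_p_cond	aa_or	aa_lo	aa_hi	aa_p	aa_p_cond
rs78545330	21995941	0.77	0.83	0.28	1.51	1.09	2.09	0.014	0.014	1.18	0.92	1.50	0.185	0.255
rs2811712	21998035	0.69	0.83	0.28	1.48	1.16	1.80	0.017	0.018	1.15	0.90	1.40	0.276	0.329
rs3218018	21998139	0.79	0.83	0.86	1.54	1.08	2.20	0.017	0.030	1.13	0.79	1.60	0.512	0.404
rs3218007	21999800	0.77	0.83	0.28	1.47	1.06	2.03	0.021	0.023	1.14	0.89	1.46	0.288	0.347
rs3218005	22000247	0.77	0.83	0.28	1.51	1.09	2.09	0.014	0.014	1.14	0.89	1.47	0.285	0.342
rs3218002	22000841	0.77	0.83	0.28	1.49	1.08	2.06	0.016	0.014	1.15	0.90	1.48	0.253	0.315
rs2069426	22006273	0.79	0.83	0.86	1.51	1.06	2.16	0.024	0.035	1.16	0.82	1.64	0.409	0.333
rs974336	22006348	0.77	0.83	0.30	1.48	1.07	2.05	0.017	0.014	1.11	0.87	1.42	0.391	0.477
rs2069422	22008026	0.70	0.83	0.86	1.47	1.12	1.82	0.028	0.042	1.28	0.92	1.64	0.179	0.157
rs77920300	22012441	0.79	0.83	0.93	1.50	1.05	2.14	0.025	0.036	1.12	0.79	1.58	0.529	0.401
rs116729641	22025432	0.79	0.83	0.86	1.48	1.04	2.12	0.029	0.043	1.12	0.79	1.58	0.537	0.409
rs77284052	22025885	0.79	0.83	0.93	1.48	1.04	2.12	0.029	0.043	1.12	0.79	1.58	0.533	0.406
rs598664	22027551	0.70	0.83	0.93	1.44	1.02	2.05	0.038	0.057	1.10	0.78	1.56	0.580	0.437
rs662463	22030438	0.70	0.83	0.58	1.45	1.03	2.06	0.034	0.051	1.55	1.16	2.06	0.003	0.002
rs79985856	22033824	0.79	0.83	0.93	1.50	1.05	2.14	0.026	0.039	1.14	0.81	1.62	0.450	0.332
rs79182326	22034267	0.69	0.70	0.93	1.41	1.00	2.00	0.049	0.073	1.15	0.81	1.63	0.425	0.297
rs76213463	22040839	0.79	0.83	0.93	1.50	1.05	2.15	0.025	0.036	1.17	0.83	1.63	0.364	0.292
rs80166549	22041155	0.79	0.83	0.93	1.51	1.05	2.15	0.024	0.035	1.14	0.81	1.59	0.454	0.379
rs1333035	22044059	0.69	0.83	0.32	1.41	1.02	1.94	0.037	0.032	1.10	0.87	1.41	0.427	0.505
rs1333034	22044122	0.70	0.83	0.93	1.48	1.05	2.10	0.026	0.039	1.12	0.80	1.57	0.500	0.413
rs17694555	22051295	0.78	0.83	0.11	1.71	1.31	2.11	0.008	0.015	1.79	0.33	3.25	0.430	0.386
rs17756311	22053895	0.77	0.83	1	1.43	0.99	2.05	0.055	0.076	1.05	0.75	1.49	0.766	0.665
rs74655961	22054164	0.77	0.83	1	1.46	1.01	2.10	0.041	0.058	1.14	0.82	1.60	0.430	0.355
rs17694572	22054356	0.77	0.83	1	1.46	1.02	2.10	0.041	0.058	1.11	0.80	1.56	0.528	0.445
rs77728904	22057530	.	.	.	1.76	1.21	2.57	0.003	0.005	1.16	0.82	1.64	0.403	0.281
rs115574830	22059061	0.87	1	1	1.70	1.17	2.48	0.005	0.007	1.26	0.90	1.76	0.186	0.120
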