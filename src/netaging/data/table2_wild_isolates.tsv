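strain	avg_rls	avg_rls_sd	network_R	network_R_sd	t0	t0_sd	n	n_sd	gompertz_R	gompertz_R_sd	gompertz_G	gompertz_G_sd	weibull_aic	weibull_aic_sd	gompertz_aic	gompertz_aic_sd	network_aic	network_aic_sd
101S	31.46	0.815	0.0025	0.0009	36	5.5	6.7	0.697	0.0012	0.00063	0.14	0.024	582.72	16.95	589.2	20.1	608.56	12.37
M1-2	27.9	1.29	0.0034	0.001	40.5	5.3	7.1	0.76	0.0026	0.00117	0.13	0.017	393.19	10.51	389.76	10.11	397.27	6.96
M13	26.6	1.064	0.0034	0.0009	40.8	4.2	7.4	0.64	0.003	0.0011	0.12	0.012	520.85	18.13	504	10.2	510.83	8.61
M14	36.32	1.621	0.0035	0.001	55.1	6.6	6.6	0.637	0.0021	0.00093	0.09	0.011	476.9	8.55	470.91	8.86	480.81	6.33
M2-8	24.77	0.733	0.0034	0.0006	42.4	4	8	0.109	0.0043	0.00104	0.12	0.011	738.35	14.92	748.01	13.64	746.64	13.4
M22	32.07	1.359	0.0033	0.001	46.3	11.8	6.9	1.508	0.002	0.00073	0.11	0.011	449.76	9.87	447.31	8.14	456.56	6.9
M32	28.15	0.973	0.0027	0.0011	34.3	2.6	7	0.714	0.0016	0.00046	0.15	0.011	402.89	10.32	411.68	8.67	419.48	9.48
M34	27.02	0.997	0.0028	0.0007	31.4	3.5	6.7	0.616	0.0013	0.0007	0.16	0.018	408.27	14.11	397.81	10.93	411.9	7.43
M5	36.85	0.942	0.0034	0.0006	74	7.2	7.8	0.381	0.004	0.00085	0.07	0.007	1321.34	14.32	1343.21	17.23	1339.61	14.58
M8	34.79	0.969	0.0018	0.0003	30.7	2.9	6.1	0.207	0.0004	0.00018	0.16	0.016	401.29	10.71	404.45	10.6	431.77	5.99
RM112N	44.13	1.751	0.0025	0.0006	55.4	6	6.2	0.375	0.0011	0.00047	0.09	0.01	470.48	11.35	466.79	10.27	481.52	6.92
S288c	26.36	1.501	0.0051	0.0017	56.8	12.9	7.9	1.341	0.0062	0.00202	0.09	0.016	309.61	9.31	310.8	8.3	312.08	8.13
SGU57	23.9	1.319	0.0065	0.0021	58	19.7	7.9	1.505	0.0077	0.00234	0.09	0.011	439.51	8.84	435.81	7.11	438.37	7.38
YPS128	35.08	1.125	0.0026	0.0008	41.9	3.9	6.5	0.486	0.0011	0.00045	0.12	0.011	507.62	12.55	506.89	11.38	522.34	8.71
YPS163	34.41	0.699	0.0023	0.0005	37.3	2.6	6.4	0.428	0.0008	0.00023	0.13	0.01	923.64	14.97	922.83	15.07	957.15	10.43
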