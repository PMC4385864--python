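gene	r_spearman	r_kendall	r_pearson	t_stat	p_value
WHSC1L1	0.737	0.604	0.460	-1.815	3.65E-02
SETD3	0.663	0.545	0.612	-4.291	2.30E-05
SETD6	0.625	0.503	0.615	4.671	5.41E-06
SETDB1	0.624	0.506	0.560	4.115	4.38E-05
SMYD4	0.614	0.498	0.626	-0.344	3.66E-01
EZH1	0.612	0.485	0.562	-6.282	6.41E-09
SUV420H1	0.553	0.448	0.599	-0.742	2.30E-01
EHMT1	0.543	0.440	0.547	-7.336	5.42E-11
SETD2	0.520	0.417	0.500	-3.102	1.30E-03
SUV39H2	0.507	0.406	0.573	8.950	2.84E-14
PRDM4	0.505	0.409	0.516	-4.631	6.31E-06
SETDB2	0.501	0.398	0.433	-2.541	6.41E-03
SETD1B	0.481	0.385	0.451	-4.121	4.29E-05
EHMT2	0.478	0.386	0.470	5.621	1.13E-07
SETD1A	0.471	0.377	0.451	0.294	3.85E-01
SETD4	0.430	0.347	0.462	0.689	2.46E-01
PRDM2	0.428	0.344	0.422	-1.400	8.25E-02
SETD5	0.418	0.337	0.469	1.931	2.84E-02
SMYD5	0.402	0.324	0.451	3.632	2.38E-04
KMT2A	0.401	0.316	0.404	0.881	1.90E-01
SETMAR	0.388	0.309	0.435	-1.719	4.46E-02
SETD8	0.367	0.292	0.387	3.239	8.50E-04
NSD1	0.358	0.283	0.387	-1.936	2.81E-02
PRDM11	0.355	0.281	0.372	1.557	6.15E-02
WHSC1	0.345	0.278	0.365	3.625	2.43E-04
SMYD2	0.343	0.270	0.336	7.273	7.23E-11
PRDM15	0.339	0.267	0.367	3.895	9.63E-05
ASH1L	0.317	0.248	0.310	-2.722	3.92E-03
SETD7	0.316	0.252	0.325	-9.245	7.08E-15
SMYD3	0.311	0.242	0.213	-6.056	1.73E-08
EZH2	0.300	0.235	0.317	8.004	2.43E-12
PRDM10	0.278	0.220	0.309	-3.070	1.43E-03
SUV420H2	0.267	0.211	0.329	-0.384	3.51E-01
KMT2C	0.261	0.205	0.262	-2.557	6.15E-03
PRDM13	0.252	0.224	0.166	4.209	3.11E-05
DOT1L	0.237	0.188	0.268	2.605	5.40E-03
PRDM7	0.227	0.200	0.177	2.538	6.47E-03
PRDM6	0.197	0.155	0.031	-6.342	4.91E-09
KMT2E	0.194	0.154	0.210	-2.351	1.05E-02
PRDM5	0.154	0.123	0.200	-0.757	2.26E-01
PRDM14	0.123	0.115	0.057	-1.054	1.47E-01
PRDM12	0.110	0.086	0.113	1.168	1.23E-01
PRDM16	0.092	0.074	0.122	0.495	3.11E-01
PRDM1	0.068	0.053	0.086	2.238	1.39E-02
SMYD1	0.063	0.050	-0.002	1.419	7.98E-02
PRDM8	0.035	0.027	0.045	0.380	3.52E-01
SUV39H1	0.016	0.011	0.077	5.415	2.69E-07
MECOM	-0.079	-0.063	-0.034	-0.261	3.97E-01
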