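gene	location	f_amp	f_gain	f_diploid	f_hetloss	f_homdel	f_mut
SMYD3	1q44	14.61	58.87	23.17	3.13	0.21	0.52
SETDB1	1q21.3	14.41	57.83	25.89	1.88	0.00	1.15
ASH1L	1q22	12.84	61.17	24.43	1.57	0.00	1.77
WHSC1L1	8p11.23	12.84	24.53	37.37	23.70	1.57	0.52
SMYD2	1q32.3	12.11	61.59	23.28	2.92	0.10	0.21
PRDM14	8q13.3	9.71	45.30	40.08	4.80	0.10	0.31
SUV420H1	11q13.2	5.64	22.65	57.41	14.20	0.10	0.84
SETD1A	16p11.2	5.01	46.87	39.77	8.35	0.00	0.42
MECOM	3q26.2	4.38	27.56	62.53	5.53	0.00	0.63
PRDM1	6q21	2.92	14.51	51.36	30.90	0.31	0.84
SUV39H2	10p13	2.82	23.90	61.48	11.69	0.10	0.10
SUV420H2	19q13.42	2.71	22.44	60.23	14.51	0.10	0.21
SETMAR	3p26.1	2.19	17.95	63.78	15.66	0.42	0.21
SETD5	3p25.3	2.09	17.85	64.61	15.34	0.10	0.52
PRDM9	5p14.2	1.88	32.05	56.05	9.81	0.21	0.73
EZH1	17q21.2	1.46	18.79	45.09	34.13	0.52	0.31
PRDM11	11p11.2	1.46	16.81	64.20	17.33	0.21	0.10
EHMT2	6p21.31	1.36	23.80	60.23	14.61	0.00	0.42
PRDM13	6q16.2	1.36	14.30	51.57	32.57	0.21	0.31
NSD1	5q35.2	1.25	24.84	55.74	17.85	0.31	1.04
PRDM15	21q22.3	1.25	20.98	61.06	16.49	0.21	0.63
PRDM16	1p36.32	0.94	7.20	52.92	38.00	0.94	0.42
SUV39H1	Xp11.23	0.94	15.34	67.01	16.28	0.42	0.21
EZH2	7q36.1	0.84	24.43	57.52	16.91	0.31	0.31
KMT2C	7q36.1	0.84	23.80	55.53	18.79	1.04	6.99
SETD4	21q22.12	0.84	20.88	62.32	15.66	0.31	0.00
PRDM7	16q24.3	0.73	8.87	26.10	61.90	2.40	0.21
SETD8	12q24.31	0.73	16.49	62.94	19.62	0.21	0.31
EHMT1	9q34.3	0.63	14.41	57.83	26.62	0.52	0.94
KMT2E	7q22.3	0.63	25.37	59.50	14.41	0.10	1.15
PRDM12	9q34.12	0.63	13.26	58.56	27.35	0.21	0.10
PRDM8	4q21.21	0.63	11.69	60.65	26.93	0.10	0.42
SETD1B	12q24.31	0.63	16.70	62.42	20.04	0.21	0.63
SETD3	14q32.2	0.63	14.30	55.74	29.02	0.31	0.31
PRDM10	11q24.3	0.52	9.50	43.63	44.78	1.57	0.73
WHSC1	4p16.3	0.52	10.13	57.41	31.21	0.73	0.42
KMT2D	12q13.12	0.42	19.73	65.76	14.09	0.00	2.40
PRDM5	4q27	0.42	10.02	60.54	29.02	0.00	0.31
DOT1L	19p13.3	0.31	10.75	56.37	31.63	0.94	0.84
PRDM4	12q23.3	0.31	16.49	64.82	18.27	0.10	0.31
PRDM6	5q23.2	0.31	18.27	57.20	23.70	0.52	0.10
SETD6	16q21	0.31	9.08	28.71	61.06	0.84	0.00
SETD7	4q31.1	0.31	9.60	60.65	29.33	0.10	0.52
SMYD4	17p13.3	0.31	6.37	34.34	58.25	0.73	0.52
SMYD5	2p13.2	0.31	16.18	68.27	15.14	0.10	0.21
PRDM2	1p36.21	0.21	5.32	53.13	40.81	0.52	0.73
SMYD1	2p11.2	0.21	15.03	69.10	15.55	0.10	0.52
KMT2A	11q23.3	0.10	9.29	41.65	48.02	0.94	1.67
SETD2	3p21.31	0.10	9.29	59.71	30.48	0.42	1.57
SETDB2	13q14.2	0.10	7.52	46.35	43.95	2.09	0.21
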