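# Reference table of the 51 human histone lysine methyltransferase genes:
# official symbol, common aliases, Entrez gene id, cytoband, histone substrates.
# Shipped for reference only; gene symbols are matched verbatim throughout the
# package (no alias resolution is applied automatically).
gene	aliases	gene_id	location	substrates
EHMT1	GLP; GLP1; KMT1D; FP13812; EUHMTASE1; Eu-HMTase1; bA188C12.1	79813	9q34.3	H3K9; H1.2K187
EHMT2	G9A; BAT8; GAT8; NG36; KMT1C; C6orf30	10919	6p21.31	H3K9; H3K27; H3K56; H1.2K187; H1.4K26
SUV39H1	MG44; KMT1A; SUV39H; H3-K9-HMTase 1	6839	Xp11.23	H3K9
SUV39H2	KMT1B	79723	10p13	H3K9
SETDB1	ESET; KG1T; KMT1E; TDRD21; H3-K9-HMTase4	9869	1q21.3	H3K9
SETDB2	CLLD8; CLLL8; KMT1F; C13orf4	83852	13q14.2	H3K9
SETD2	HYPB; SET2; HIF-1; HIP-1; KMT3A; HBP231; HSPC069; p231HBP	29072	3p21.31	H3K36
KMT2E	MLL5; NKp44L; HDCMC04P	55904	7q22.3	H3K4
SETD5		55209	3p25.3
SETMAR	Mar1; HsMar1; METNASE	6419	3p26.1	H3K36
EZH1	KMT6B	2145	17q21.2	H3K27
EZH2	WVS; ENX1; EZH1; KMT6; WVS2; ENX-1; EZH2b; KMT6A	2146	7q36.1	H3K27
SETD7	KMT7; SET7; SET9; SET7/9	80854	4q31.1	H3K4
KMT2B	HRX2; MLL2; MLL4; TRX2; WBP7; MLL1B; WBP-7	9757	19q13.12	H3K4
KMT2C	HALR; MLL3	58508	7q36.1	H3K4
SETD1A	Set1; KMT2F; Set1A	9739	16p11.2	H3K4
SETD1B	KMT2G; Set1B	23067	12q24.31	H3K4
KMT2A	HRX; MLL; MLL1; TRX1; ALL-1; CXXC7; HTRX1; MLL1A; WDSTS; MLL/GAS7; TET1-MLL	4297	11q23.3	H3K4
KMT2D	ALR; KMS; MLL2; MLL4; AAD10; KABUK1; TNRC21; CAGL114	8085	12q13.12	H3K4
SETD8	SET8; KMT5A; SET07; PR-Set7	387893	12q24.31	H4K20
MECOM	EVI1; MDS1; PRDM3; MDS1-EVI1; AML1-EVI-1	2122	3q26.2	H3K9me1
PRDM16	MEL1; LVNC8; PFM13; CMD1LL	63976	1p36.32	H3K9me1
PRDM13	PFM10; MU-MB-20.220	59336	6q16.2
PRDM8	PFM5	56978	4q21.21	H3K9
PRDM1	BLIMP1; PRDI-BF1	639	6q21
PRDM2	RIZ; KMT8; RIZ1; RIZ2; MTB-ZF; HUMHOXY1	7799	1p36.21	H3K9
PRDM10	PFM7	56980	11q24.3
PRDM12	PFM9	59335	9q34.12
PRDM6		93166	5q23.2
PRDM14	PFM11	63978	8q13.3
PRDM4	PFM1	11108	12q23.3
PRDM15	PFM15; ZNF298; C21orf83	63977	21q22.3
PRDM5	BCS2; PFM2	11107	4q27
PRDM7	PFM4; ZNF910	11105	16q24.3
PRDM9	PFM6; MSBP3; PRMD9; ZNF899; MEISETZ	56979	5p14.2	H3K4
PRDM11	PFM8	56981	11p11.2
SUV420H1	CGI85; KMT5B; CGI-85	51111	11q13.2	H4K20
SUV420H2	KMT5C	84787	19q13.42	H4K20
ASH1L	ASH1; KMT2H; ASH1L1	55870	1q22	H3K4; H3K36
SETD3	C14orf154	84193	14q32.2
SETD4	C21orf18; C21orf27	54093	21q22.12
SETD6		79918	16q21
SMYD1	BOP; KMT3D; ZMYND18; ZMYND22	150572	2p11.2	H3K4
SMYD3	KMT3E; ZMYND1; ZNFN3A1; bA74P14.1	64754	1q44	H3K4
SMYD2	KMT3C; HSKM-B; ZMYND14	56950	1q32.3	H3K4; H3K36
SMYD4	ZMYND21	114826	17p13.3
SMYD5	RRG1; RAI15; NN8-4AG; ZMYND23	10322	2p13.2
NSD1	STO; KMT3B; SOTOS; ARA267; SOTOS1	64324	5q35.2	H3K36
WHSC1	WHS; NSD2; TRX5; MMSET; REIIBP	7468	4p16.3	H3K36; H4K20
WHSC1L1	NSD3; pp14328	54904	8p11.23	H3K4; H3K27
DOT1L	DOT1; KMT4	84444	19p13.3	H3K79
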