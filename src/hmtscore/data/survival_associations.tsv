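# Per-gene minimum pairwise log-rank p-values from the 770-sample TCGA
# overall-survival analysis.  analysis: cna = amp/gain vs diploid vs deletion
# groups; expr = median split of expression z-scores.
# For the cna rows only the set of genes reaching significance below 0.05 is
# reported in the source; p=0.049 is a SYNTHETIC placeholder strictly below
# that level, used only for threshold comparisons.  expr rows carry reported
# p-values.
gene	analysis	p	p_is_placeholder
KMT2C	cna	0.049	1
SETDB2	cna	0.049	1
SETD2	cna	0.049	1
SETMAR	cna	0.049	1
PRDM1	cna	0.049	1
PRDM5	cna	0.049	1
PRDM8	cna	0.049	1
WHSC1L1	expr	0.0231	0
SETD7	expr	0.0021	0
SETD5	expr	0.0456	0
SUV39H2	expr	0.0506	0
KMT2A	expr	0.0644	0
NSD1	expr	0.0701	0
ASH1L	expr	0.0877	0
SETD8	expr	0.0769	0
EHMT2	expr	0.0978	0
KMT2C	expr	0.3774	0
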