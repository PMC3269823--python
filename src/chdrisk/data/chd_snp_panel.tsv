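rsid	chrom	gene	risk_allele	or_point	or_lower	or_upper	raf_reported	raf_observed
rs10757278	9	CDKN2A/2B	G	1.28	1.22	1.35	0.45	0.52
rs599839	1	SORT1	A	1.17	1.11	1.22	0.78	0.78
rs3008621	1	MIA3	G	1.11	1.04	1.19	0.26	NA
rs501120	10	Unknown	T	1.30	1.12	1.51	0.84	0.87
rs9818870	3	MRAS	T	1.15	1.11	1.19	0.15	0.15
rs3184504	12	SH2B3	T	1.13	1.08	1.18	0.39	0.49
rs9982601	21	MRPS6	T	1.20	1.14	1.27	0.13	0.14
rs12526453	6	PHACTR1	C	1.12	1.08	1.17	0.65	0.67
rs6725887	2	WDR12	C	1.17	1.11	1.23	0.14	0.13
rs1122608	19	LDLR	G	1.15	1.10	1.21	0.75	0.77
rs11206510	1	PCSK9	T	1.15	1.10	1.21	0.81	0.82
rs1746048	10	CXCL12	C	1.16	1.09	1.24	0.84	0.87
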