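gene_id_gs	gene_id_gr	label	annotation	start_gs	start_gr	stop_gs	stop_gr	logfc	pvalue
EleInSChr3g081370	EleInRChr3_2g092340	EPSPS	EPSPS	1669076	2165535	1673225	2169359	4.6	1.6e-11
EleInSChr3g081410	EleInRChr3_2g092360	A410	Ribosomal subunit protein	1673439	2169409	1675161	2171640	5.8	2.8e-11
EleInSChr3g081390	EleInRChr3_2g092350	A390	tRNA 2'-phosphotransferase 1	1675833	2172099	1680441	2176989	4.6	4.9e-13
EleInSChr3g081400	None	A400	Unknown protein	1682414	2178757	1687866	2184208	1.2	0.42
EleInSChr3g081440	EleInRChr3_2g080580	A440	Unknown protein of E. coracana	1695565	2192031	1701288	2198135	5.2	3e-14
EleInSChr3g082510	EleInRChr3_2g221600	B510	DNA repair protein RadA-like	2724808	3211487	2735415	3224071	5.2	6.9e-11
EleInSChr3g082560	EleInRChr3_2g119210	B560	6-phosphofructokinase 1 (PFK)	2742394	3229211	2747873	3234785	0.41	0.78
EleInSChr3g082520	NotAnnotatedInR	B520	Putative dual specificity protein phosphatase DSP8	2748924	3235752	2752196	3239024	1.1	0.03
EleInSChr3g082570	EleInRChr3_2g091630	B570	E3 ubiquitin-protein ligase 1	2758205	3245033	2759136	3245964	-	-
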