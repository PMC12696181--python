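#CHROM	POS	REF	ALT-INSERTION	INFO	Accession	Function
CM032588.1	693243	C	CAGTCATGGCCTCAACCACAACGCATCTGCATCTAGATGGTCT	TYPE=INSERT	QYS95571.1	Translation factor GUF1, mitochondrial
CM032588.1	1014012	t	ttcgtcttcgtcctttgccttgtcttcgtct	TYPE=INSERT	QYS95678.1	Hypothetical protein
CM032588.1	3932529	C	CCGACAACAAGTCAGAGAGACTGTTAATCAACAATACCAACAGAT	TYPE=INSERT	QYS96675.1	Hypothetical protein
CM032588.1	4294894	G	GGCTCGGACGCACTACGTGAGCCGGCTACGAGTGTTTTGAGCACCTCGGAAGGACAACAACATCAGCAA	TYPE=INSERT	QYS96808.1	Zn(2)-C6 fungal-type domain-containing protein
CM032588.1	6884912	C	CTACACGACGAGCTGTGGCGCAGCGAGATCAGAATCGCGAGCGAGACGATGCT	TYPE=INSERT	QYS97733.1	Phosphatidylglycerophosphate synthase
CM032591.1	1709627	C	CTTGGACCTATCCCAGACTTGGACCTATCCCAGAC	TYPE=INSERT	QYT02427.1	Hypothetical protein
CM032591.1	2509827	A	ACCATTGAGAAAGTAAAGGGAAACGATGATGGACA	TYPE=INSERT	QYT02698.1	Hypothetical protein
CM032593.1	742413	A	ACAACCCCAGGCTCCTCCTGTCACTCAAATCAGCGATGGT	TYPE=INSERT	QYT05221.1	Hypothetical protein
CM032593.1	742452	T	TGGccagcctcaagctcctccCGTTACTCAAATCAGCGAC	TYPE=INSERT	QYT05221.1	Hypothetical protein
CM032593.1	1045489	A	AGAAGTCTACTGAGCTCCTGATCCGCAAGCTACCCTTCCAGCGTCTNGGTAAGAAcacgaagccatcaccacccaCTGATCGTCGCNNNTATGTTCCACAGCCAACAAGCCTCACCGTTATAAACCTGATACCGTCGCCCTCCGTGAGATTCGTCGATACCA	TYPE=INSERT	QYT05335.1	Histone H3
CM032593.1	1052881	A	AGGAGATCGCCGCCAGTTGTTGTGTTTGTCAGATTCCCAATTACTCCTCCAAGGTCGGTGTTATTCAATAGTCCCCCTGTTCCAACACCAAGAGTACTGTTCAATAGACCTTCTGTTCCTGCTCCTAATCCGCCAGTCGCTGTGGAGTTGTCAGGGGTCCCAGGTCCTAATAATCCTCCCA	TYPE=INSERT	QYT05335.1	Histone H3
CM032593.1	1855174	g	gatttttgcttttgcttcttcaagtcTTTTTCGAGCTTATCCGCgt	TYPE=INSERT	QYT05340.1	Hypothetical protein
CM032593.1	2369775	G	GGCCCTCATCCATATGGCCCTCATCCATATA	TYPE=INSERT	QYT05648.1	GPI inositol-deacylase
CM032593.1	3703706	G	gttgttgttgatgctgatgacgaagttgatgatg	TYPE=INSERT	QYT05811.1	Hypothetical protein
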