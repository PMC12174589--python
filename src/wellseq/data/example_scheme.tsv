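direction	index	barcode	primer
F	1	GACAG	GTGTCAGCAGCCGCGGTAA
F	2	GTGAT	GTGTCAGCAGCCGCGGTAA
F	3	GAGTA	GTGTCAGCAGCCGCGGTAA
F	4	AATGA	GTGTCAGCAGCCGCGGTAA
F	5	CCCAC	GTGTCAGCAGCCGCGGTAA
F	6	CAGGG	GTGTCAGCAGCCGCGGTAA
F	7	CGAAA	GTGTCAGCAGCCGCGGTAA
F	8	CCTAG	GTGTCAGCAGCCGCGGTAA
F	9	TATGT	GTGTCAGCAGCCGCGGTAA
F	10	GGAAC	GTGTCAGCAGCCGCGGTAA
F	11	TACAT	GTGTCAGCAGCCGCGGTAA
F	12	CCTTC	GTGTCAGCAGCCGCGGTAA
R	1	GGTCC	GGACTACACGGGTATCTAAT
R	2	CCGAG	GGACTACACGGGTATCTAAT
R	3	GTTCG	GGACTACACGGGTATCTAAT
R	4	GCATA	GGACTACACGGGTATCTAAT
R	5	AAGCA	GGACTACACGGGTATCTAAT
R	6	ATGTT	GGACTACACGGGTATCTAAT
R	7	GCCAG	GGACTACACGGGTATCTAAT
R	8	TACGA	GGACTACACGGGTATCTAAT
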