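# Top 20 8-mers of S. cerevisiae ORF-upstream regions (500 bp), order-4 Markov
# background ranked by Z-score (published reference list).
1	GCGATGAG
2	TAATATTA
3	CCTCGAGG
4	CGGTGTTA
5	GTTACCCG
6	GGAAGCTG
7	CTCGAGGA
8	CGGGTAAC
9	CCGGGTAA
10	CTAGTATA
11	ACTTCTAG
12	CTCATCGC
13	TCCTCGAG
14	GATTCCTA
15	AAAAGAAA
16	GAAGCTGA
17	GGATTCCT
18	TACGGTGT
19	TTACCCGG
20	AGGAGAAC
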