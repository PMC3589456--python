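# Top 20 8-mers of S. cerevisiae ORF-upstream regions (500 bp), order-4 Markov
# background ranked by binomial probability (published reference list).
1	TAATATTA
2	GCGATGAG
3	AAAAGAAA
4	CGGTGTTA
5	CCTCGAGG
6	GGAAGCTG
7	GTTACCCG
8	CTCGAGGA
9	CTAGTATA
10	TTTCTTTT
11	ACTTCTAG
12	CTCATCGC
13	CCGGGTAA
14	CGGGTAAC
15	TGATAATG
16	GAAGCTGA
17	TCCTCGAG
18	AGGAGAAC
19	GATTCCTA
20	GGATTCCT
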