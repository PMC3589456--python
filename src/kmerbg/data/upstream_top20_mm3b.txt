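# Top 20 8-mers of S. cerevisiae ORF-upstream regions (500 bp), order-3 Markov
# background ranked by binomial probability (published reference list).
1	TATATATA
2	ATATATAT
3	GCGATGAG
4	TTTTTTTC
5	GAAAAAAA
6	AAAAGAAA
7	CCTCGAGG
8	CTCGAGGA
9	GTTACCCG
10	CTCATCGC
11	TTTCTTTT
12	CATATATA
13	CCGGGTAA
14	ATATGTAT
15	ATACATAT
16	TCCTCGAG
17	TATACATA
18	CGGGTAAC
19	TTACCCGG
20	TATGTATA
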