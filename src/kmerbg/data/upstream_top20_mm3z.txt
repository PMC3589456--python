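# Top 20 8-mers of S. cerevisiae ORF-upstream regions (500 bp), order-3 Markov
# background ranked by Z-score (published reference list).
1	TATATATA
2	GCGATGAG
3	ATATATAT
4	CCTCGAGG
5	GTTACCCG
6	CTCGAGGA
7	CCGGGTAA
8	CTCATCGC
9	CGGGTAAC
10	TCCTCGAG
11	TTACCCGG
12	CGATGAGC
13	TTTTTTTC
14	GAAAAAAA
15	GATGAGCT
16	GGAAGCTG
17	ATATGTAT
18	ATTACCCG
19	CGGTGTTA
20	AAAAGAAA
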