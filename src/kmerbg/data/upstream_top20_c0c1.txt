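# Top 20 8-mers of S. cerevisiae ORF-upstream regions (500 bp), single-mismatch
# (C0/C1) background, ranked by decreasing fold enrichment (published reference list).
1	CCTCGAGG
2	GCGATGAG
3	TAGCCGCC
4	CTCGAGGA
5	CGGTGTTA
6	TCCTCGAG
7	TACGGTGT
8	GGCGGCTA
9	CCGGGTAA
10	GGAAGCTG
11	GTTACCCG
12	ATACGGTG
13	TTACCCGG
14	TTTTTTTC
15	TCCGGGTA
16	CGGGTAAC
17	CGATGAGC
18	GAAAAAAA
19	CTCATCGC
20	ATTACCCG
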