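# Top 20 8-mers of S. cerevisiae ORF-upstream regions (500 bp), average-(k-1)-mer
# background, ranked by decreasing fold enrichment (published reference list).
1	CCTCGAGG
2	GCGATGAG
3	CCCAGCGC
4	CCGAGTGG
5	GGAAGCTG
6	TCCTCGAG
7	CGCGTCGC
8	CTCGAGGA
9	GATGAGCT
10	GATGACGC
11	ATACGGTG
12	GCGCGCGC
13	GCGCCCGC
14	TAGCCGCC
15	GCGACGCG
16	CACGTGAC
17	GGATTCCT
18	GCCCCCGG
19	GGCGCGTC
20	ACGCAAGG
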