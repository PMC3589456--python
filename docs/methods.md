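# Methods

## Counting

A word's count is the **maximum number of mutually non-overlapping
occurrences**, realized by greedy left-to-right scanning (after a match at
position *i*, scanning resumes at *i + k*). For fixed-length matches the
greedy schedule provably attains the maximum, which has two useful
consequences: the count is reproducible regardless of scan direction, and it
is invariant under reverse complementation of the text, so strand-aggregated
tables satisfy `counts[w] == counts[revcomp(w)]` exactly. Matches never span
two FASTA records; records are counted independently and summed.

Strand aggregation (`strand_policy="both"`, the default) adds each word's
greedy count over the forward residues and over the reverse-complemented
residues. A word and its reverse complement remain distinct table keys (each
carrying the same aggregated count); they are not collapsed into a canonical
key, because published word lists are oriented.

N handling: any window containing N is skipped, and N is excluded from
mononucleotide denominators. IUPAC ambiguity codes other than N are read as
N (with a warning); RNA and non-nucleotide characters are rejected.

Normalization totals — *N* for (k−1)-mers and *M* for k-mers — are the sums
of the non-overlapping tables themselves, not the number of overlapping
window positions. This is the self-consistent choice: with it, word
frequencies computed from a table sum to exactly 1, and the model's worked
small cases (below) close exactly. The overlapping-positions alternative is
not exposed as a default anywhere.

Implementation: windows are 2-bit encoded with numpy and sorted by word
code; a short greedy selection kernel (numba-jitted when numba imports,
with an identical pure-Python fallback) picks each word's non-overlapping
subset in one pass. This keeps a full 3 Mb benchmark run at a few seconds.

## The average (k−1)-mer background

Expected counts are reconstructed from the model's verbal definition:
frequency of the (k−1)-mer subword × frequency of the remaining
mononucleotide × number of k-mer slots, once for the prefix+last-base
decomposition (E₁) and once for the first-base+suffix decomposition (E₂).
Fold enrichment is the average of O/E₁ and O/E₂.

The Z-score is `(O − Ē)/√Ē` with `Ē = (E₁+E₂)/2`: a **Poisson variance**
approximation, the simplest spread model consistent with count data. A
binomial variance `Ē(1 − Ē/M)` is available via `variance="binomial"`; for
rare words the two are numerically indistinguishable, and in the degenerate
case Ē = M (single-word input) the binomial variance vanishes and Z is
defined as 0 when O = Ē.

Closed-form checks used in the tests: on a forward-strand homopolymer the
model is exact (E₁ = E₂ = O, F = 1, Z = 0). Under both-strand counting a
pure homopolymer instead gives F = 2 exactly — the complementary strand
halves both the subword frequency and the base frequency — so the
homopolymer calibration is asserted on the forward strand, and the
both-strand F = 2 limit is pinned as its own regression test.

Only observed words are scored; absent-word statistics are out of scope.

## Single-mismatch (C0/C1) background

The expectation for a word is the arithmetic mean of the counts of its 3k
single-substitution neighbors (the word itself excluded), with `F = C₀/C₁`
and `Z = (C₀ − C₁)/√C₁`. No pseudocount is added by default — a word whose
entire neighborhood is unobserved yields an undefined record rather than an
arbitrary score — but an additive pseudocount parameter is available.

## Markov backgrounds

For order *m* the word probability is estimated from the (m+1)-mer table:

    P(w) = n(w[0:m+1])/T · Π_i  n(w[i:i+m+1]) / ctx(w[i:i+m])

where *T* is the total (m+1)-mer count and `ctx(c) = Σ_b n(c·b)` is the
context total summed over observed extensions, and `E(w) = M_k · P(w)`.
Taking context totals from the (m+1)-mer table itself (rather than from a
separate m-mer table) keeps the chain properly normalized under
non-overlapping counting: transition probabilities out of each context sum
to 1 over observed extensions. Two consequences are tested: at m = 0 the
expectation reduces to the Bernoulli composition product `M_k·Πp(bᵢ)`, and
at the maximal order m = k−2 on a homopolymer the chain reproduces the
observed count exactly.

Markov records always carry the **exact binomial upper tail**
`P(X ≥ O), X ~ Binomial(M_k, E/M_k)` as their p-value; the normal-theory
`Z = (O−E)/√(E(1−E/M))` is a separate field used when Z-ranking is
requested. Exact reproduction of any particular external oligo-analysis
implementation is a non-goal; the backgrounds here are estimated from the
same non-overlapping, strand-aggregated tables as everything else.

## Significance and ranking

Only overrepresentation is tested (one-sided upper tail). The Bonferroni
test count defaults to the number of distinct observed words scored at that
k — only hypotheses actually tested are corrected for — with 4^k available
as a stricter alternative (`n_tests_mode="all"` in the survey). Rankings
sort by descending fold or Z (ascending binomial p), with ties broken by
descending Z then lexicographic word order, so all outputs are
byte-deterministic.

## Cross-species bin comparison

Each species' defined records are split into `n_bins` (default 8)
equal-width bins of the fold score spanning **that species' own fold
range**; bins correspond across species by index, not by shared numeric
edges — species with different score ranges therefore have different bin
widths, which is the intended semantics of comparing relative enrichment
strata. Bins are half-open `[lo, hi)` with the last bin closed so the
maximum-fold word is always binned; a degenerate all-equal fold range is
widened by machine epsilon into a single occupied bin. A reference word
counts as shared in bin *i* only if it appears in bin *i* of **every**
species in the combination (intersection semantics), so adding a species can
only keep or lower a percentage. Empty reference bins report a missing
value, not 0%. Words with undefined scores in a species are excluded from
that species' partition.

## Synthetic data

`random_sequences` draws iid bases with P(G)=P(C)=gc/2; the benchmark
default gc = 0.38 matches the genomic GC content of *S. cerevisiae*.
`implant_motif` overwrites uniformly random non-overlapping windows rather
than inserting, keeping the stated sequence length; one implant per
sequence is the default. The benchmark's two RNG streams derive from the
config seed (seed for generation, seed+1 for placement), making a run a
pure function of its config.

`synthetic_species` produces one ancestral iid genome and per-species iid
substitutions (a substituted base becomes one of the 3 other bases,
uniformly), giving the closed-form pairwise identity
`(1−r)² + r²/3` used in the tests. It deliberately omits indels, rate
heterogeneity and phylogenetic structure: it exists to exercise the
comparison machinery, not to emulate evolution. Accordingly, passing tests
demonstrate correctness of the counting/scoring/binning pipeline, not that
the model recovers biology from real genomes — real inputs are supplied as
ordinary FASTA files.

## Problem sizes

The full benchmark (6,000 × 500 bp) is used wherever its result is the
claim under test: five seeds for the implantation ranks and twenty seeds
for the null calibration (zero implants; the motif must be non-significant
after Bonferroni at α = 0.05 in ≥ 95% of seeds). Law-of-large-numbers and
identity calibrations use 1 Mb fixtures; comparison-pipeline properties use
20–100 kb genomes, where the asserted properties are scale-free.

## Known limitations

* For small k in large genomes nearly every observed word is called
  overrepresented under the average (k−1)-mer model (the subword context is
  too weak a constraint until observed counts diverge from the 4^k
  saturation regime); the model is most informative once k is large enough
  that not all words are near-saturated.
* The Z-score's Poisson variance understates dispersion for highly periodic
  words under non-overlapping counting.
* The fold-rank of an implanted motif is realization-dependent: rare words
  with tiny expectations can exceed its fold score, which is why the
  benchmark's stable claim is the Z-rank, not the fold-rank.
* C0/C1 neighborhoods use the plain mean of neighbor counts; no
  regression-style reweighting of neighbors is attempted.
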