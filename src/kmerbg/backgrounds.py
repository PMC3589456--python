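"""Null models for k-mer overrepresentation.

Three backgrounds are implemented:

* **ak1** — the average-(k-1)-mer model. The expected count of a word is
  estimated twice, once from each of its two (k-1)-mer subwords (prefix and
  suffix): the subword's frequency among all (k-1)-mers is multiplied by the
  frequency of the remaining mononucleotide and by the total number of
  observed k-mer occurrences. The two fold enrichments F1 = O/E1 and
  F2 = O/E2 are averaged into the reported fold score, and the Z-score is
  computed against the average expected count E-bar = (E1+E2)/2.

  The published description of this model names E-bar but not a variance, so
  the Z denominator here is a reconstruction: sqrt(E-bar), the Poisson
  approximation — the simplest variance model for count data. A binomial
  variance sqrt(E-bar * (1 - E-bar/M)) is available via ``variance=``; the
  two differ negligibly for rare words.

* **c0c1** — the classical single-mismatch neighborhood model: the
  expectation for a word is the arithmetic mean C1 of the counts of its 3k
  single-substitution neighbors; enrichment is C0/C1, Z = (C0-C1)/sqrt(C1).

* **markov** — a maximum-likelihood Markov chain of order m estimated from
  the same strand-aggregated non-overlapping tables. The word probability is
  taken from the (m+1)-mer table (initial factor and transitions with
  context totals summed over extensions) and scaled by the number of k-mer
  slots M_k. Ranking can use Z or the exact binomial upper tail.

All models score *observed* words only (absent words are out of scope), and
all use one-sided upper-tail p-values: only overrepresentation is called.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

from scipy import stats as _sps

from .counting import (
    KmerCountTable,
    MonoFrequencies,
    StrandPolicy,
    build_count_table,
    mono_frequencies,
)
from .seqio import SequenceSet

Model = Literal["ak1", "c0c1", "markov"]
RankStatistic = Literal["fold", "zscore", "binomial"]

_NAN = float("nan")
_SQRT2 = math.sqrt(2.0)


def _norm_sf(z: float) -> float:
    """Upper-tail standard normal probability (scalar, erfc-based)."""
    return 0.5 * math.erfc(z / _SQRT2)


@dataclass
class BackgroundSpec:
    """Choice of null model plus its parameters."""

    model: Model = "ak1"
    markov_order: int | None = None
    rank_statistic: RankStatistic = "fold"

    def __post_init__(self) -> None:
        if self.model not in ("ak1", "c0c1", "markov"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.model == "markov":
            if self.markov_order is None or self.markov_order < 0:
                raise ValueError("markov model requires markov_order >= 0")
        elif self.markov_order is not None:
            raise ValueError("markov_order only applies to the markov model")
        if self.rank_statistic not in ("fold", "zscore", "binomial"):
            raise ValueError(f"unknown rank statistic {self.rank_statistic!r}")
        if self.rank_statistic == "binomial" and self.model != "markov":
            raise ValueError("binomial ranking is defined for the markov model only")


@dataclass
class EnrichmentRecord:
    """One scored k-mer: observed count, expectations, fold scores, Z, p.

    ``defined`` is False when a denominator vanished (zero expectation with a
    positive observed count); such records carry NaN scores and are never
    called significant. For the single-expectation models (c0c1, markov)
    E1 == E2 == E-bar and F1 == F2 == fold.
    """

    kmer: str
    observed: int
    expected_1: float
    expected_2: float
    expected_mean: float
    fold_1: float
    fold_2: float
    fold: float
    zscore: float
    pvalue: float
    significant: bool = False
    defined: bool = True


def _undefined(kmer: str, observed: int, e1: float, e2: float) -> EnrichmentRecord:
    return EnrichmentRecord(
        kmer=kmer,
        observed=observed,
        expected_1=e1,
        expected_2=e2,
        expected_mean=(e1 + e2) / 2.0,
        fold_1=_NAN,
        fold_2=_NAN,
        fold=_NAN,
        zscore=_NAN,
        pvalue=_NAN,
        defined=False,
    )


# ---------------------------------------------------------------------------
# average-(k-1)-mer model


def ak1_expected(
    kmer: str,
    table_k: KmerCountTable,
    table_km1: KmerCountTable,
    mono: MonoFrequencies,
) -> tuple[float, float]:
    """Expected counts (E1, E2) of *kmer* from its two (k-1)-mer subwords.

    E1 pairs the prefix (k-1)-mer with the appended final base; E2 pairs the
    suffix (k-1)-mer with the prepended first base:

        E1 = (C1 / N) * p(last base)  * M
        E2 = (C2 / N) * p(first base) * M

    with C1, C2 the subword counts, N the total (k-1)-mer occurrences and M
    the total k-mer occurrences.
    """
    kmer = kmer.upper()
    if len(kmer) != table_k.k or table_km1.k != table_k.k - 1:
        raise ValueError("table lengths must be k and k-1 for a length-k word")
    n_km1 = table_km1.total_occurrences
    m_k = table_k.total_occurrences
    if n_km1 == 0 or m_k == 0:
        raise ValueError("empty tables")
    c1 = table_km1.get(kmer[:-1])
    c2 = table_km1.get(kmer[1:])
    e1 = (c1 / n_km1) * mono[kmer[-1]] * m_k
    e2 = (c2 / n_km1) * mono[kmer[0]] * m_k
    return e1, e2


def _ak1_record(
    kmer: str,
    observed: int,
    e1: float,
    e2: float,
    m_k: int,
    variance: str,
) -> EnrichmentRecord:
    if (e1 == 0.0 or e2 == 0.0) and observed > 0:
        return _undefined(kmer, observed, e1, e2)
    ebar = (e1 + e2) / 2.0
    f1 = observed / e1 if e1 > 0 else 0.0
    f2 = observed / e2 if e2 > 0 else 0.0
    fold = (f1 + f2) / 2.0
    if variance == "poisson":
        var = ebar
    elif variance == "binomial":
        var = ebar * (1.0 - ebar / m_k)
    else:
        raise ValueError(f"unknown variance model {variance!r}")
    if var > 0:
        z = (observed - ebar) / math.sqrt(var)
    elif observed == ebar:  # degenerate variance (e.g. E == M under binomial)
        z = 0.0
    else:
        z = math.copysign(math.inf, observed - ebar)
    p = _norm_sf(z) if not math.isnan(z) else _NAN
    return EnrichmentRecord(
        kmer=kmer,
        observed=observed,
        expected_1=e1,
        expected_2=e2,
        expected_mean=ebar,
        fold_1=f1,
        fold_2=f2,
        fold=fold,
        zscore=z,
        pvalue=p,
        defined=not math.isnan(z),
    )


def ak1_score(
    kmer: str,
    table_k: KmerCountTable,
    table_km1: KmerCountTable,
    mono: MonoFrequencies,
    variance: str = "poisson",
) -> EnrichmentRecord:
    """Score one word under the average-(k-1)-mer model."""
    kmer = kmer.upper()
    e1, e2 = ak1_expected(kmer, table_k, table_km1, mono)
    return _ak1_record(kmer, table_k.get(kmer), e1, e2, table_k.total_occurrences, variance)


def ak1_scores(
    table_k: KmerCountTable,
    table_km1: KmerCountTable,
    mono: MonoFrequencies,
    variance: str = "poisson",
) -> list[EnrichmentRecord]:
    """Score every observed word of the k-table (bulk form of ak1_score)."""
    n_km1 = table_km1.total_occurrences
    m_k = table_k.total_occurrences
    if n_km1 == 0 or m_k == 0:
        raise ValueError("empty tables")
    sub = table_km1.counts
    freq = mono.freq
    out = []
    for kmer, observed in table_k.counts.items():
        e1 = (sub.get(kmer[:-1], 0) / n_km1) * freq[kmer[-1]] * m_k
        e2 = (sub.get(kmer[1:], 0) / n_km1) * freq[kmer[0]] * m_k
        out.append(_ak1_record(kmer, observed, e1, e2, m_k, variance))
    return out


# ---------------------------------------------------------------------------
# single-mismatch (C0/C1) model


def mismatch_neighbors(kmer: str) -> list[str]:
    """The 3k single-substitution neighbors of *kmer* (word itself excluded)."""
    out = []
    for i, orig in enumerate(kmer):
        for base in "ACGT":
            if base != orig:
                out.append(kmer[:i] + base + kmer[i + 1 :])
    return out


def c0c1_score(
    kmer: str, table_k: KmerCountTable, pseudocount: float = 0.0
) -> EnrichmentRecord:
    """Score one word against the mean count of its single-mismatch neighbors."""
    kmer = kmer.upper()
    if len(kmer) != table_k.k:
        raise ValueError("word length does not match table")
    counts = table_k.counts
    observed = counts.get(kmer, 0)
    neighbors = mismatch_neighbors(kmer)
    c1 = sum(counts.get(nb, 0) for nb in neighbors) / len(neighbors) + pseudocount
    if c1 == 0.0:
        return _undefined(kmer, observed, 0.0, 0.0)
    fold = observed / c1
    z = (observed - c1) / math.sqrt(c1)
    return EnrichmentRecord(
        kmer=kmer,
        observed=observed,
        expected_1=c1,
        expected_2=c1,
        expected_mean=c1,
        fold_1=fold,
        fold_2=fold,
        fold=fold,
        zscore=z,
        pvalue=_norm_sf(z),
    )


def c0c1_scores(
    table_k: KmerCountTable, pseudocount: float = 0.0
) -> list[EnrichmentRecord]:
    return [c0c1_score(w, table_k, pseudocount) for w in table_k.counts]


# ---------------------------------------------------------------------------
# Markov background


class MarkovBackground:
    """Order-m Markov null estimated from strand-aggregated count tables.

    The probability of a word w of length k is

        P(w) = n(w[0:m+1]) / T * prod_i n(w[i:i+m+1]) / ctx(w[i:i+m])

    where n(.) are (m+1)-mer counts, T their total, and ctx(c) the count of
    context c summed over its observed single-base extensions. Expected count
    is E(w) = M_k * P(w), so expectations over all words scale to M_k.
    """

    def __init__(
        self,
        seqs: SequenceSet,
        k: int,
        order: int,
        strand_policy: StrandPolicy = "both",
        table_k: KmerCountTable | None = None,
    ) -> None:
        if order < 0:
            raise ValueError("markov order must be >= 0")
        if order > k - 2:
            raise ValueError("order too high for word length (need order <= k-2)")
        self.k = k
        self.order = order
        self.table_k = table_k if table_k is not None else build_count_table(seqs, k, strand_policy)
        self.table_sub = build_count_table(seqs, order + 1, strand_policy)
        self._context: dict[str, int] = {}
        for word, cnt in self.table_sub.counts.items():
            ctx = word[:-1]
            self._context[ctx] = self._context.get(ctx, 0) + cnt

    def expected(self, kmer: str) -> float:
        """Expected count of *kmer* under the chain; 0 if a factor is unobserved."""
        kmer = kmer.upper()
        if len(kmer) != self.k:
            raise ValueError("word length does not match background")
        m = self.order
        sub = self.table_sub.counts
        total = self.table_sub.total_occurrences
        first = sub.get(kmer[: m + 1], 0)
        if first == 0:
            return 0.0
        prob = first / total
        for i in range(1, self.k - m):
            num = sub.get(kmer[i : i + m + 1], 0)
            if num == 0:
                return 0.0
            ctx = self._context.get(kmer[i : i + m], 0)
            if ctx == 0:
                raise ValueError(f"zero context count for {kmer[i:i+m]!r}")
            prob *= num / ctx
        return self.table_k.total_occurrences * prob

    def score(self, kmer: str, rank_statistic: RankStatistic = "zscore") -> EnrichmentRecord:
        kmer = kmer.upper()
        observed = self.table_k.get(kmer)
        e = self.expected(kmer)
        m_k = self.table_k.total_occurrences
        if e == 0.0:
            return _undefined(kmer, observed, 0.0, 0.0)
        fold = observed / e
        var = e * (1.0 - e / m_k)
        z = (observed - e) / math.sqrt(var) if var > 0 else _NAN
        p_rate = min(e / m_k, 1.0)
        pvalue = float(_sps.binom.sf(observed - 1, m_k, p_rate))
        return EnrichmentRecord(
            kmer=kmer,
            observed=observed,
            expected_1=e,
            expected_2=e,
            expected_mean=e,
            fold_1=fold,
            fold_2=fold,
            fold=fold,
            zscore=z,
            pvalue=pvalue,
        )


def markov_expected(kmer: str, seqs: SequenceSet, order: int,
                    strand_policy: StrandPolicy = "both") -> float:
    """Convenience wrapper: expected count of one word (builds tables)."""
    return MarkovBackground(seqs, len(kmer), order, strand_policy).expected(kmer)


def markov_score(
    kmer: str,
    seqs: SequenceSet,
    order: int,
    rank_statistic: RankStatistic = "zscore",
    strand_policy: StrandPolicy = "both",
) -> EnrichmentRecord:
    return MarkovBackground(seqs, len(kmer), order, strand_policy).score(kmer, rank_statistic)


def markov_scores(
    seqs: SequenceSet,
    k: int,
    order: int,
    rank_statistic: RankStatistic = "zscore",
    strand_policy: StrandPolicy = "both",
    table_k: KmerCountTable | None = None,
) -> list[EnrichmentRecord]:
    bg = MarkovBackground(seqs, k, order, strand_policy, table_k=table_k)
    return [bg.score(w, rank_statistic) for w in bg.table_k.counts]


# ---------------------------------------------------------------------------
# dispatcher


def score_sequences(
    seqs: SequenceSet,
    k: int,
    spec: BackgroundSpec | None = None,
    strand_policy: StrandPolicy = "both",
    variance: str = "poisson",
) -> list[EnrichmentRecord]:
    """Score all observed k-mers of *seqs* under the chosen background."""
    spec = spec or BackgroundSpec()
    if spec.model == "ak1":
        table_k = build_count_table(seqs, k, strand_policy)
        table_km1 = build_count_table(seqs, k - 1, strand_policy)
        mono = mono_frequencies(seqs, strand_policy)
        return ak1_scores(table_k, table_km1, mono, variance)
    if spec.model == "c0c1":
        return c0c1_scores(build_count_table(seqs, k, strand_policy))
    return markov_scores(seqs, k, spec.markov_order, spec.rank_statistic, strand_policy)


def write_enrichment_tsv(
    records: Sequence[EnrichmentRecord],
    path: str | Path,
    spec: BackgroundSpec | None = None,
    header_extra: str = "",
) -> None:
    """Serialize enrichment records to TSV with a '#' metadata header."""
    with open(path, "w") as fh:
        if spec is not None:
            order = f" order={spec.markov_order}" if spec.markov_order is not None else ""
            fh.write(f"# model={spec.model}{order} stat={spec.rank_statistic}{header_extra}\n")
        fh.write(
            "kmer\tobserved\tE1\tE2\tE_mean\tF1\tF2\tfold\tzscore\tpvalue"
            "\tsignificant\tdefined\n"
        )
        for r in records:
            fh.write(
                f"{r.kmer}\t{r.observed}\t{r.expected_1:.6g}\t{r.expected_2:.6g}"
                f"\t{r.expected_mean:.6g}\t{r.fold_1:.6g}\t{r.fold_2:.6g}\t{r.fold:.6g}"
                f"\t{r.zscore:.6g}\t{r.pvalue:.6g}\t{int(r.significant)}\t{int(r.defined)}\n"
            )
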