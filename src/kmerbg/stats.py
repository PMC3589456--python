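"""Significance calling, ranked lists, and list-level summaries.

Overrepresentation is called one-sided (upper tail) with an optional
Bonferroni correction whose default test count is the number of distinct
observed words actually scored at that length — only scored hypotheses are
corrected for; the 4^k alternative is available for sensitivity checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

from .backgrounds import (
    BackgroundSpec,
    EnrichmentRecord,
    RankStatistic,
    score_sequences,
)
from .counting import StrandPolicy
from .seqio import SequenceSet


@dataclass
class SignificanceConfig:
    """Significance level, correction scheme and number of tests."""

    n_tests: int
    alpha: float = 0.05
    correction: str = "bonferroni"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_tests < 1:
            raise ValueError("n_tests must be >= 1")
        if self.correction not in ("bonferroni", "none"):
            raise ValueError(f"unknown correction {self.correction!r}")

    @property
    def threshold(self) -> float:
        return self.alpha / self.n_tests if self.correction == "bonferroni" else self.alpha


def call_overrepresented(
    records: Sequence[EnrichmentRecord], config: SignificanceConfig
) -> Sequence[EnrichmentRecord]:
    """Set the ``significant`` flag on each record (in place; also returned)."""
    threshold = config.threshold
    for rec in records:
        rec.significant = bool(
            rec.defined and math.isfinite(rec.pvalue) and rec.pvalue < threshold
        )
    return records


@dataclass
class RankedList:
    """Enrichment records sorted by one statistic (deterministic tie-break)."""

    k: int
    records: list[EnrichmentRecord]
    statistic: RankStatistic


def _sort_key(statistic: RankStatistic):
    def key(rec: EnrichmentRecord):
        if not rec.defined:
            return (1, 0.0, 0.0, rec.kmer)
        z = -rec.zscore if math.isfinite(rec.zscore) else 0.0
        if statistic == "fold":
            return (0, -rec.fold, z, rec.kmer)
        if statistic == "zscore":
            return (0, z, z, rec.kmer)
        return (0, rec.pvalue, z, rec.kmer)  # binomial: ascending p

    return key


def rank_records(
    records: Iterable[EnrichmentRecord], statistic: RankStatistic = "fold"
) -> RankedList:
    """Sort records by descending fold or Z (ascending binomial p).

    Undefined records sink to the end; ties break by descending Z then by
    lexicographic word order, so output is deterministic.
    """
    records = list(records)
    if statistic not in ("fold", "zscore", "binomial"):
        raise ValueError(f"unknown rank statistic {statistic!r}")
    ordered = sorted(records, key=_sort_key(statistic))
    k = len(ordered[0].kmer) if ordered else 0
    return RankedList(k=k, records=ordered, statistic=statistic)


def top_n(ranked: RankedList, n: int) -> list[str]:
    """The first min(n, size) words of the ranked list."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return [rec.kmer for rec in ranked.records[:n]]


def rank_of(ranked: RankedList, word: str) -> int:
    """1-based rank of *word* in the list (KeyError if absent)."""
    word = word.upper()
    for i, rec in enumerate(ranked.records, start=1):
        if rec.kmer == word:
            return i
    raise KeyError(f"{word!r} not in ranked list")


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal round-half-up, for display figures like mean GC%."""
    quant = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quant, rounding=ROUND_HALF_UP))


def mean_gc_percent(words: Sequence[str]) -> float:
    """Unweighted mean GC percentage over a list of words (full precision)."""
    if not words:
        raise ValueError("empty word list")
    fracs = [
        100.0 * sum(1 for b in w.upper() if b in "GC") / len(w) for w in words
    ]
    return sum(fracs) / len(fracs)


def list_overlap(
    reference: Sequence[str],
    other: Sequence[str],
    skip_top: int = 0,
) -> tuple[list[tuple[str, int, int]], int]:
    """Words shared between two ranked lists, with ranks in each.

    When ``skip_top`` > 0 the first skip_top ranks of BOTH lists are excluded
    before intersecting (used to count shared words "beyond the identical top
    ranks"). Returns (shared, count) with shared = [(word, rank_ref,
    rank_other), ...] ordered by reference rank; ranks are 1-based positions
    in the full lists.
    """
    ref = [w.upper() for w in reference]
    oth = [w.upper() for w in other]
    ref_rank = {w: i for i, w in enumerate(ref, start=1)}
    oth_rank = {w: i for i, w in enumerate(oth, start=1)}
    shared = [
        (w, ref_rank[w], oth_rank[w])
        for w in ref
        if w in oth_rank and ref_rank[w] > skip_top and oth_rank[w] > skip_top
    ]
    return shared, len(shared)


def survey_spectrum(
    seqs: SequenceSet,
    k_range: Iterable[int],
    spec: BackgroundSpec | None = None,
    alpha: float = 0.05,
    correction: str = "bonferroni",
    n_tests_mode: str = "observed",
    strand_policy: StrandPolicy = "both",
) -> list[dict]:
    """Per-k spectrum summary: distinct words, words seen >= 2x, significant.

    For each k the observed words are scored under *spec* (ak1 by default)
    and called at *alpha* after correction; ``n_tests_mode`` picks the test
    count ('observed' distinct words, or 'all' = 4^k).
    """
    spec = spec or BackgroundSpec()
    if n_tests_mode not in ("observed", "all"):
        raise ValueError("n_tests_mode must be 'observed' or 'all'")
    if spec.model == "ak1":
        min_k = 2  # needs a (k-1)-mer table
    elif spec.model == "markov":
        min_k = (spec.markov_order or 0) + 2
    else:
        min_k = 1
    rows = []
    for k in k_range:
        if k >= min_k:
            records = score_sequences(seqs, k, spec, strand_policy)
            counts = {r.kmer: r.observed for r in records}
            n_tests = len(records) if n_tests_mode == "observed" else 4**k
            call_overrepresented(
                records,
                SignificanceConfig(n_tests=max(n_tests, 1), alpha=alpha, correction=correction),
            )
            overrepresented = sum(1 for r in records if r.significant)
        else:  # word too short for this background: count, don't score
            from .counting import build_count_table

            counts = build_count_table(seqs, k, strand_policy).counts
            overrepresented = None
        rows.append(
            {
                "k": k,
                "distinct": len(counts),
                "ge2": sum(1 for c in counts.values() if c >= 2),
                "overrepresented": overrepresented,
                "theoretical_max": 4**k,
            }
        )
    return rows


def write_survey_tsv(rows: Sequence[dict], path: str | Path, header_extra: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(f"#{header_extra}\n" if header_extra else "# spectrum survey\n")
        fh.write("k\tdistinct\tge2\toverrepresented\ttheoretical_max\n")
        for row in rows:
            over = "NA" if row["overrepresented"] is None else row["overrepresented"]
            fh.write(
                f"{row['k']}\t{row['distinct']}\t{row['ge2']}"
                f"\t{over}\t{row['theoretical_max']}\n"
            )
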