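"""Cross-species comparison of fold-score ranked k-mer lists.

Each species' scored words are split into equal-width bins of the fold
enrichment score, where the bin edges span that species' OWN fold range
(bins correspond by index across species, not by shared numeric edges).
For every combination of non-reference species, the per-bin overlap profile
reports the percentage of reference-bin words present in the same-index bin
of every species in the combination.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .backgrounds import BackgroundSpec, EnrichmentRecord, score_sequences
from .counting import StrandPolicy
from .seqio import SequenceSet


@dataclass
class BinPartition:
    """Equal-width fold-score bins and their word membership for one list."""

    n_bins: int
    edges: np.ndarray  # n_bins + 1 ascending floats
    members: list[set[str]]
    source_label: str = ""

    def __post_init__(self) -> None:
        if len(self.edges) != self.n_bins + 1:
            raise ValueError("edges must have n_bins + 1 entries")
        widths = np.diff(self.edges)
        if not np.allclose(widths, widths[0], atol=1e-9):
            raise ValueError("bin edges are not equally spaced")


@dataclass
class OverlapProfile:
    """Per-bin percentage of reference words shared with every other list.

    ``per_bin[i]`` is None (missing, not 0) when the reference bin is empty.
    """

    reference_label: str
    other_labels: tuple[str, ...]
    per_bin: list[float | None]
    ref_counts: list[int]
    shared_counts: list[int]


def make_bins(
    records: Sequence[EnrichmentRecord], n_bins: int = 8, source_label: str = ""
) -> BinPartition:
    """Partition defined records into equal-width fold-score bins.

    Bins are [edge_i, edge_{i+1}) with the last bin closed on the right so
    the maximum-fold word is always binned. A degenerate span (all folds
    equal) is widened by machine epsilon into a single occupied bin.
    """
    defined = [r for r in records if r.defined and math.isfinite(r.fold)]
    if not defined:
        raise ValueError("no defined records to bin")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    folds = np.array([r.fold for r in defined], dtype=float)
    lo, hi = float(folds.min()), float(folds.max())
    if hi <= lo:
        hi = lo + max(np.spacing(lo), np.spacing(0.0))
    edges = np.linspace(lo, hi, n_bins + 1)
    span = hi - lo
    idx = np.floor((folds - lo) / span * n_bins).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)
    members: list[set[str]] = [set() for _ in range(n_bins)]
    for rec, i in zip(defined, idx):
        members[i].add(rec.kmer)
    return BinPartition(n_bins=n_bins, edges=edges, members=members, source_label=source_label)


def overlap_profile(
    reference: BinPartition, others: Sequence[BinPartition] | BinPartition
) -> OverlapProfile:
    """Per-bin identity percentages of the reference against other partitions.

    A reference word counts as shared in bin i only if it is present in bin i
    of EVERY other partition (intersection semantics).
    """
    if isinstance(others, BinPartition):
        others = [others]
    if not others:
        raise ValueError("need at least one partition to compare against")
    for other in others:
        if other.n_bins != reference.n_bins:
            raise ValueError("bin count mismatch between partitions")
    per_bin: list[float | None] = []
    ref_counts: list[int] = []
    shared_counts: list[int] = []
    for i in range(reference.n_bins):
        ref = reference.members[i]
        ref_counts.append(len(ref))
        if not ref:
            per_bin.append(None)
            shared_counts.append(0)
            continue
        shared = set(ref)
        for other in others:
            shared &= other.members[i]
        shared_counts.append(len(shared))
        per_bin.append(100.0 * len(shared) / len(ref))
    return OverlapProfile(
        reference_label=reference.source_label,
        other_labels=tuple(o.source_label for o in others),
        per_bin=per_bin,
        ref_counts=ref_counts,
        shared_counts=shared_counts,
    )


def _combinations(labels: Sequence[str]) -> list[tuple[str, ...]]:
    out: list[tuple[str, ...]] = []
    for size in range(1, len(labels) + 1):
        out.extend(itertools.combinations(sorted(labels), size))
    return out


def run_comparison(
    species: Mapping[str, SequenceSet],
    k: int,
    reference_label: str,
    spec: BackgroundSpec | None = None,
    n_bins: int = 8,
    strand_policy: StrandPolicy = "both",
) -> dict[tuple[str, ...], OverlapProfile]:
    """Bin-overlap profiles for every species combination with the reference.

    Scores each species at length *k* under *spec* (ak1 by default), bins the
    defined words by that species' own fold range, and intersects the
    reference bins against every non-empty subset of the other species
    (enumerated by size, then lexicographically).
    """
    if len(species) < 2:
        raise ValueError("need at least 2 species")
    if reference_label not in species:
        raise ValueError(f"reference {reference_label!r} not among inputs")
    partitions = {
        label: make_bins(
            score_sequences(seqs, k, spec, strand_policy), n_bins, source_label=label
        )
        for label, seqs in species.items()
    }
    others = [lab for lab in species if lab != reference_label]
    return {
        combo: overlap_profile(partitions[reference_label], [partitions[lab] for lab in combo])
        for combo in _combinations(others)
    }


def write_profile_tsv(
    profile: OverlapProfile, reference: BinPartition, path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"# reference={profile.reference_label} "
            f"others={','.join(profile.other_labels)} n_bins={reference.n_bins}\n"
        )
        fh.write("bin_index\tref_bin_lo\tref_bin_hi\tref_count\tshared_count\tpercent\n")
        for i, pct in enumerate(profile.per_bin):
            pct_txt = "NA" if pct is None else f"{pct:.4f}"
            fh.write(
                f"{i}\t{reference.edges[i]:.6g}\t{reference.edges[i + 1]:.6g}"
                f"\t{profile.ref_counts[i]}\t{profile.shared_counts[i]}\t{pct_txt}\n"
            )
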