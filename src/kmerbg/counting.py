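"""Non-overlapping, strand-aggregated k-mer occurrence tables.

"Non-overlapping" is realized as greedy left-to-right scanning: after a match
at position i the scan resumes at i + k. For equal-length intervals the greedy
schedule attains the maximum number of mutually non-overlapping occurrences,
which also makes the count invariant under reverse complementation of the
text. Windows containing N never match; matches never span two records.

The per-word public function :func:`count_nonoverlapping` is a plain string
scan. :func:`build_count_table` counts every observed word of one length in a
single pass: windows are 2-bit encoded with numpy, sorted by word code, and a
greedy selection kernel (numba-jitted when available) picks the non-overlapping
subset per word.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np

from .seqio import SequenceSet, reverse_complement

StrandPolicy = Literal["both", "forward"]

_ENCODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
_DECODE_LUT = np.frombuffer(b"ACGT", dtype=np.uint8)


def _check_strand_policy(strand_policy: str) -> str:
    if strand_policy not in ("both", "forward"):
        raise ValueError(f"strand_policy must be 'both' or 'forward', got {strand_policy!r}")
    return strand_policy


def _greedy_select_py(codes: np.ndarray, pos: np.ndarray, k: int) -> np.ndarray:
    mask = np.zeros(codes.size, dtype=np.bool_)
    last_code = np.int64(-1)
    last_end = np.int64(-1)
    for i in range(codes.size):
        c = codes[i]
        p = pos[i]
        if c != last_code:
            last_code = c
            mask[i] = True
            last_end = p + k
        elif p >= last_end:
            mask[i] = True
            last_end = p + k
    return mask


try:  # optional jit; the pure-python loop is the reference behavior
    from numba import njit as _njit

    _greedy_select = _njit(cache=False)(_greedy_select_py)
except Exception:  # pragma: no cover - exercised only without numba
    _greedy_select = _greedy_select_py


@dataclass
class KmerCountTable:
    """Aggregated non-overlapping counts for all observed words of length k.

    ``total_occurrences`` (M_k) is the sum of the table's counts; at length
    k-1 it plays the role of the normalization total N for the subword
    frequencies of the average-(k-1)-mer background.
    """

    k: int
    counts: dict[str, int]
    total_occurrences: int
    region_length: int
    strand_policy: str = "both"

    def get(self, word: str) -> int:
        """Observed count O of *word* (0 if never observed)."""
        return self.counts.get(word.upper(), 0)

    def __contains__(self, word: str) -> bool:
        return word.upper() in self.counts

    def __len__(self) -> int:
        return len(self.counts)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# k={self.k} total={self.total_occurrences} "
                f"length={self.region_length} strands={self.strand_policy}\n"
            )
            fh.write("kmer\tcount\n")
            for word in sorted(self.counts):
                fh.write(f"{word}\t{self.counts[word]}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "KmerCountTable":
        meta: dict[str, str] = {}
        counts: dict[str, int] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    for item in line[1:].split():
                        if "=" in item:
                            key, val = item.split("=", 1)
                            meta[key] = val
                elif line and not line.startswith("kmer\t"):
                    word, cnt = line.split("\t")
                    counts[word] = int(cnt)
        return cls(
            k=int(meta["k"]),
            counts=counts,
            total_occurrences=int(meta["total"]),
            region_length=int(meta["length"]),
            strand_policy=meta.get("strands", "both"),
        )


@dataclass
class MonoFrequencies:
    """Mononucleotide fractions among non-N residues (sum to 1)."""

    freq: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.freq.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mononucleotide fractions sum to {total}, expected 1")
        if any(v < 0 for v in self.freq.values()):
            raise ValueError("negative mononucleotide fraction")

    def __getitem__(self, base: str) -> float:
        return self.freq[base]


def count_nonoverlapping(sequence: str, word: str) -> int:
    """Greedy left-to-right count of non-overlapping occurrences of *word*.

    Greedy scanning attains the maximum count for fixed-length matches.
    Windows containing N never match (the word itself is A/C/G/T only).
    """
    if not word:
        raise ValueError("empty word")
    word = word.upper()
    if set(word) - set("ACGT"):
        raise ValueError(f"word {word!r} must be over A/C/G/T")
    sequence = sequence.upper()
    count = 0
    start = 0
    while True:
        idx = sequence.find(word, start)
        if idx < 0:
            return count
        count += 1
        start = idx + len(word)


def _window_codes(encoded: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Base-4 codes and start positions of every N-free window of length k."""
    n = encoded.size - k + 1
    if n <= 0:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty
    enc = encoded.astype(np.int64)
    codes = np.zeros(n, dtype=np.int64)
    for j in range(k):
        codes = codes * 4 + enc[j : j + n]
    bad = np.concatenate(([0], np.cumsum((encoded < 0).astype(np.int64))))
    valid = (bad[k:] - bad[:-k]) == 0
    pos = np.nonzero(valid)[0].astype(np.int64)
    return codes[valid], pos


def _decode_codes(codes: np.ndarray, k: int) -> list[str]:
    out = np.empty((codes.size, k), dtype=np.uint8)
    tmp = codes.copy()
    for j in range(k - 1, -1, -1):
        out[:, j] = _DECODE_LUT[(tmp & 3).astype(np.intp)]
        tmp >>= 2
    raw = out.tobytes()
    return [raw[i * k : (i + 1) * k].decode("ascii") for i in range(codes.size)]


def _count_strand(texts: list[str], k: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-word greedy non-overlapping counts over a list of texts."""
    all_codes: list[np.ndarray] = []
    all_pos: list[np.ndarray] = []
    offset = 0
    for text in texts:
        encoded = _ENCODE[np.frombuffer(text.encode("ascii"), dtype=np.uint8)]
        codes, pos = _window_codes(encoded, k)
        all_codes.append(codes)
        all_pos.append(pos + offset)
        offset += len(text) + k  # gap: a match can never span two records
    codes = np.concatenate(all_codes) if all_codes else np.empty(0, np.int64)
    pos = np.concatenate(all_pos) if all_pos else np.empty(0, np.int64)
    if codes.size == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    order = np.argsort(codes, kind="stable")  # stable keeps positions ascending
    codes_sorted = codes[order]
    pos_sorted = pos[order]
    mask = _greedy_select(codes_sorted, pos_sorted, k)
    selected = codes_sorted[mask]
    return np.unique(selected, return_counts=True)


def build_count_table(
    seqs: SequenceSet, k: int, strand_policy: StrandPolicy = "both"
) -> KmerCountTable:
    """Count every observed word of length *k*, aggregating both strands.

    Under ``strand_policy='both'`` each word's count is its greedy
    non-overlapping count over the forward residues plus over the
    reverse-complemented residues, so counts[w] == counts[revcomp(w)].
    Words never observed are simply absent (queries return 0).
    """
    _check_strand_policy(strand_policy)
    if k < 1:
        raise ValueError("k must be >= 1")
    if all(len(r) < k for r in seqs):
        raise ValueError("k exceeds all sequence lengths")

    counts: dict[str, int] = {}
    passes = [[r.residues for r in seqs]]
    if strand_policy == "both":
        passes.append([reverse_complement(r.residues) for r in seqs])
    for texts in passes:
        uniq, cnt = _count_strand(texts, k)
        for word, c in zip(_decode_codes(uniq, k), cnt):
            counts[word] = counts.get(word, 0) + int(c)

    return KmerCountTable(
        k=k,
        counts=counts,
        total_occurrences=sum(counts.values()),
        region_length=seqs.total_length,
        strand_policy=strand_policy,
    )


def mono_frequencies(
    seqs: SequenceSet, strand_policy: StrandPolicy = "both"
) -> MonoFrequencies:
    """Base fractions among non-N residues (complement-pooled under 'both')."""
    _check_strand_policy(strand_policy)
    tallies = np.zeros(4, dtype=np.int64)
    for rec in seqs:
        encoded = _ENCODE[np.frombuffer(rec.residues.encode("ascii"), dtype=np.uint8)]
        tallies += np.bincount(encoded[encoded >= 0], minlength=4)
    total = int(tallies.sum())
    if total == 0:
        raise ValueError("no A/C/G/T residues (all-N input)")
    a, c, g, t = (float(x) for x in tallies)
    if strand_policy == "both":
        a = t = (a + t) / 2.0
        c = g = (c + g) / 2.0
    return MonoFrequencies(freq={"A": a / total, "C": c / total, "G": g / total, "T": t / total})
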