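"""Reading and writing DNA sequence sets and k-mer lists.

Sequences are held as plain uppercase strings over the alphabet {A,C,G,T,N}.
IUPAC ambiguity codes other than N are downgraded to N with a warning so real
assemblies parse; RNA (U) and non-nucleotide characters are rejected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

DNA_ALPHABET = frozenset("ACGTN")

_AMBIGUITY = "RYSWKMBDHV"
_AMBIGUITY_TO_N = str.maketrans(_AMBIGUITY, "N" * len(_AMBIGUITY))
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def normalize_residues(raw: str, context: str = "") -> str:
    """Uppercase *raw* and map ambiguity codes to N.

    Raises ValueError for U (RNA) and for anything that is not an IUPAC
    nucleotide code (digits, punctuation, gaps).
    """
    seq = raw.upper()
    if "U" in seq:
        raise ValueError(f"RNA residue 'U' not allowed{context}")
    seq2 = seq.translate(_AMBIGUITY_TO_N)
    bad = set(seq2) - DNA_ALPHABET
    if bad:
        raise ValueError(
            f"illegal residue(s) {sorted(bad)!r}{context}; expected IUPAC nucleotide codes"
        )
    if seq2 != seq:
        warnings.warn(
            f"ambiguity codes converted to N{context}", UserWarning, stacklevel=2
        )
    return seq2


@dataclass
class SequenceRecord:
    """One named DNA sequence (uppercase, {A,C,G,T,N})."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"record {self.id!r}: residues empty")
        bad = set(self.residues) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: residues not normalized, found {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class SequenceSet:
    """An ordered collection of SequenceRecords, e.g. one species or region."""

    records: list[SequenceRecord]
    label: str = ""

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate record ids in set {self.label!r}")
        if self.total_length == 0:
            raise ValueError(f"sequence set {self.label!r} has no residues")

    @property
    def total_length(self) -> int:
        """Total residue count L of the region (N included)."""
        return sum(len(r) for r in self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _find_bad_line(path: str | Path) -> int | None:
    """Locate the first FASTA body line holding a non-IUPAC character."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith((">", ";")):
                continue
            try:
                normalize_residues(line)
            except ValueError:
                return lineno
    return None


def read_fasta(path: str | Path, label: str | None = None) -> SequenceSet:
    """Parse a (multi-)FASTA file into a SequenceSet.

    Residues are uppercased; ambiguity codes become N (warning); digits or
    punctuation raise a parse error that names the offending line.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            residues = normalize_residues(str(rec.seq), context=f" in record {rec.id!r}")
        except ValueError as exc:
            lineno = _find_bad_line(path)
            where = f" ({path}:{lineno})" if lineno is not None else f" ({path})"
            raise ValueError(f"FASTA parse error{where}: {exc}") from exc
        records.append(SequenceRecord(id=rec.id, residues=residues))
    if not records:
        raise ValueError(f"no sequences in {path}")
    return SequenceSet(records=records, label=label if label is not None else path.stem)


def write_fasta(seqs: SequenceSet, path: str | Path, width: int = 70) -> None:
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description="") for r in seqs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def reverse_complement(word: str) -> str:
    """Watson-Crick reverse complement; N maps to N."""
    w = word.upper()
    bad = set(w) - DNA_ALPHABET
    if bad:
        raise ValueError(f"non-DNA character(s) {sorted(bad)!r} in {word!r}")
    return w.translate(_COMPLEMENT)[::-1]


def read_kmer_list(path: str | Path) -> list[str]:
    """Read an ordered k-mer list: one word per line, optional leading rank.

    Words are validated against {A,C,G,T}. Mixed word lengths are allowed but
    reported through the warnings channel; invalid characters are fatal.
    """
    words: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            word = fields[1] if len(fields) >= 2 and fields[0].isdigit() else fields[0]
            word = word.upper()
            if set(word) - set("ACGT"):
                raise ValueError(
                    f"invalid k-mer {word!r} at {path}:{lineno} (expected A/C/G/T only)"
                )
            words.append(word)
    if len({len(w) for w in words}) > 1:
        warnings.warn(f"mixed word lengths in {path}", UserWarning, stacklevel=2)
    return words


def write_kmer_list(words: Iterable[str], path: str | Path, ranks: bool = True) -> None:
    with open(path, "w") as fh:
        for i, w in enumerate(words, start=1):
            fh.write(f"{i}\t{w}\n" if ranks else f"{w}\n")
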