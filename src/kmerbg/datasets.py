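"""Packaged reference k-mer lists.

Six published top-20 8-mer rankings of S. cerevisiae ORF-upstream regions
(500 bp) under different background models, used as worked examples for the
list-comparison utilities (mean GC content, ranked-list overlap).
"""

from __future__ import annotations

from importlib import resources

from .seqio import read_kmer_list

REFERENCE_METHODS = ("ak1", "c0c1", "mm4z", "mm4b", "mm3z", "mm3b")


def load_top20(method: str) -> list[str]:
    """Load one packaged top-20 list by method tag (see REFERENCE_METHODS)."""
    method = method.lower()
    if method not in REFERENCE_METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {REFERENCE_METHODS}")
    ref = resources.files("kmerbg") / "data" / f"upstream_top20_{method}.txt"
    with resources.as_file(ref) as path:
        return read_kmer_list(path)


def load_all_top20() -> dict[str, list[str]]:
    return {m: load_top20(m) for m in REFERENCE_METHODS}
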