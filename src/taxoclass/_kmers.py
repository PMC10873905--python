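"""Canonical k-mer primitives shared by the curation and classification stages.

A canonical k-mer is the lexicographic minimum of a k-mer and its reverse
complement, which makes every downstream statistic strand-agnostic. K-mers
containing any base outside ACGT (e.g. N) are skipped.
"""

from __future__ import annotations

from typing import Iterator

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
_VALID = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved per-base)."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    rc = kmer.translate(_COMPLEMENT)[::-1]
    return kmer if kmer <= rc else rc


def iter_canonical(seq: str, k: int) -> Iterator[str]:
    """Yield the canonical form of every ACGT-only k-mer window of ``seq``."""
    seq = seq.upper()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if _VALID.issuperset(kmer):
            yield canonical(kmer)


def canonical_set(seq: str, k: int) -> set[str]:
    return set(iter_canonical(seq, k))


def canonical_multiset(seq: str, k: int) -> list[str]:
    return list(iter_canonical(seq, k))
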