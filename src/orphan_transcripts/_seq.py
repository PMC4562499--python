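"""Small nucleotide-string helpers shared across the pipeline."""

from __future__ import annotations

from typing import Iterable, Iterator

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMP)[::-1]


def iter_kmers(seq: str, k: int) -> Iterator[str]:
    """Yield every k-mer of ``seq`` that contains no uncalled (N) base.

    N bases contribute no k-mers: ambiguity cannot provide mapping evidence.
    """
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" not in kmer:
            yield kmer


def kmer_set(seqs: Iterable[str], k: int, both_strands: bool = True) -> set[str]:
    """The set of k-mers over a collection of sequences.

    With ``both_strands`` the set is strand-symmetric (contains the k-mers of
    each sequence and of its reverse complement).
    """
    out: set[str] = set()
    for s in seqs:
        out.update(iter_kmers(s, k))
        if both_strands:
            out.update(iter_kmers(revcomp(s), k))
    return out
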