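"""Screening of paired-end reads down to high-quality pairs with both ends unmapped.

The cascade mirrors the standard pre-processing of unmapped-read mining:

1. quality filtering (uncalled bases, sliding-window mean phred),
2. duplicate (clone) removal on the *pair* of sequences,
3. removal of any pair where either mate maps to a reference tier.

Mapping here is a deterministic exact-k-mer rule (default seed length k=28):
a mate "maps" when it shares at least one k-mer, on either strand, with any
reference tier.  Real-data users who already have alignments take the
:func:`ingest_sam` path instead, which keeps pairs whose SAM flags say both
ends are unmapped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import iter_kmers, kmer_set, revcomp

logger = logging.getLogger(__name__)

DEFAULT_K = 28
DEFAULT_PHRED = 17
DEFAULT_WINDOW_FRAC = 0.15


@dataclass(frozen=True)
class ReadPair:
    """A mate pair: two sequences with per-base phred qualities."""

    pair_id: str
    seq1: str
    seq2: str
    qual1: tuple[int, ...]
    qual2: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.qual1) != len(self.seq1) or len(self.qual2) != len(self.seq2):
            raise ValueError(f"pair {self.pair_id}: quality/sequence length mismatch")


@dataclass
class KmerIndex:
    """Strand-symmetric exact k-mer sets over named reference tiers."""

    k: int = DEFAULT_K
    tiers: dict[str, set[str]] = field(default_factory=dict)

    def add_tier(self, name: str, seqs: Iterable[str]) -> None:
        self.tiers[name] = kmer_set(seqs, self.k, both_strands=True)

    @classmethod
    def from_fastas(cls, paths: Sequence[str | Path], k: int = DEFAULT_K) -> "KmerIndex":
        idx = cls(k=k)
        for p in paths:
            idx.add_tier(Path(p).stem, (str(r.seq).upper() for r in SeqIO.parse(str(p), "fasta")))
        return idx

    def hit_tier(self, seq: str) -> str | None:
        """Name of the first tier sharing a k-mer with ``seq`` (either strand), else None."""
        if len(seq) < self.k:
            logger.warning("read shorter than k=%d contributes no k-mers", self.k)
            return None
        for name, kmers in self.tiers.items():
            for km in iter_kmers(seq, self.k):
                if km in kmers:
                    return name
        return None


@dataclass
class ScreenStats:
    """Per-stage accounting; input = retained + sum of removals."""

    input: int = 0
    low_quality: int = 0
    clones: int = 0
    mapped_by_tier: dict[str, int] = field(default_factory=dict)
    retained: int = 0

    @property
    def mapped(self) -> int:
        return sum(self.mapped_by_tier.values())

    def check(self) -> None:
        if self.input != self.retained + self.low_quality + self.clones + self.mapped:
            raise AssertionError("screening accounting violated")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("stage\tcount\n")
            fh.write(f"input\t{self.input}\n")
            fh.write(f"low_quality\t{self.low_quality}\n")
            fh.write(f"clones\t{self.clones}\n")
            for tier, n in sorted(self.mapped_by_tier.items()):
                fh.write(f"mapped_{tier}\t{n}\n")
            fh.write(f"retained\t{self.retained}\n")


def quality_filter(
    pair: ReadPair,
    window_frac: float = DEFAULT_WINDOW_FRAC,
    phred_threshold: float = DEFAULT_PHRED,
) -> bool:
    """Keep a pair only if both mates are clean.

    A mate fails if it contains an uncalled base (N) or if any sliding window
    of length ceil(window_frac * read_len) has mean phred below the threshold.
    """
    if not 0 < window_frac <= 1:
        raise ValueError("window_frac must be in (0, 1]")
    for seq, qual in ((pair.seq1, pair.qual1), (pair.seq2, pair.qual2)):
        if not seq:
            raise ValueError(f"pair {pair.pair_id}: empty sequence")
        if "N" in seq:
            return False
        w = math.ceil(window_frac * len(seq))
        run = sum(qual[:w])
        if run < phred_threshold * w:
            return False
        for i in range(w, len(qual)):
            run += qual[i] - qual[i - w]
            if run < phred_threshold * w:
                return False
    return True


def clone_filter(pairs: Iterable[ReadPair]) -> list[ReadPair]:
    """One representative per distinct (seq1, seq2); first seen wins, order kept."""
    seen: set[tuple[str, str]] = set()
    out: list[ReadPair] = []
    for p in pairs:
        key = (p.seq1, p.seq2)
        if key not in seen:
            seen.add(key)
            out.append(p)
    return out


def classify_pair(pair: ReadPair, index: KmerIndex) -> str:
    """'mapped' iff either mate shares a k-mer with any tier; else 'unmapped'.

    Only pairs with *both* ends unmapped survive screening.
    """
    if not index.tiers:
        raise ValueError("classify_pair requires at least one index tier")
    if index.hit_tier(pair.seq1) is not None or index.hit_tier(pair.seq2) is not None:
        return "mapped"
    return "unmapped"


def screen_library(
    pairs: Iterable[ReadPair],
    index: KmerIndex,
    window_frac: float = DEFAULT_WINDOW_FRAC,
    phred_threshold: float = DEFAULT_PHRED,
) -> tuple[list[ReadPair], ScreenStats]:
    """quality_filter -> clone_filter -> both-ends-unmapped, with accounting."""
    stats = ScreenStats()
    hq: list[ReadPair] = []
    for p in pairs:
        stats.input += 1
        if quality_filter(p, window_frac, phred_threshold):
            hq.append(p)
        else:
            stats.low_quality += 1
    unique = clone_filter(hq)
    stats.clones = len(hq) - len(unique)
    retained: list[ReadPair] = []
    for p in unique:
        tier = index.hit_tier(p.seq1) or index.hit_tier(p.seq2)
        if tier is None:
            retained.append(p)
        else:
            stats.mapped_by_tier[tier] = stats.mapped_by_tier.get(tier, 0) + 1
    stats.retained = len(retained)
    stats.check()
    return retained, stats


# ---------------------------------------------------------------------------
# FASTQ / SAM input and output
# ---------------------------------------------------------------------------

def read_fastq_pairs(path1: str | Path, path2: str | Path) -> list[ReadPair]:
    """Load mate pairs from two phred+33 FASTQ files (the /1 and /2 convention)."""
    pairs = []
    it1 = SeqIO.parse(str(path1), "fastq")
    it2 = SeqIO.parse(str(path2), "fastq")
    for r1, r2 in zip(it1, it2, strict=True):
        pid = r1.id.removesuffix("/1")
        pairs.append(
            ReadPair(
                pair_id=pid,
                seq1=str(r1.seq).upper(),
                seq2=str(r2.seq).upper(),
                qual1=tuple(r1.letter_annotations["phred_quality"]),
                qual2=tuple(r2.letter_annotations["phred_quality"]),
            )
        )
    return pairs


def write_fastq_pairs(pairs: Iterable[ReadPair], path1: str | Path, path2: str | Path) -> None:
    recs1, recs2 = [], []
    for p in pairs:
        r1 = SeqRecord(Seq(p.seq1), id=f"{p.pair_id}/1", description="")
        r1.letter_annotations["phred_quality"] = list(p.qual1)
        r2 = SeqRecord(Seq(p.seq2), id=f"{p.pair_id}/2", description="")
        r2.letter_annotations["phred_quality"] = list(p.qual2)
        recs1.append(r1)
        recs2.append(r2)
    SeqIO.write(recs1, str(path1), "fastq")
    SeqIO.write(recs2, str(path2), "fastq")


def ingest_sam(path: str | Path) -> list[ReadPair]:
    """Extract pairs whose SAM flags mark both ends unmapped.

    Sequences are reverse-complemented back to original read orientation when
    the reverse-strand flag is set.  Orphan mates are dropped with a warning.
    """
    first: dict[str, pysam.AlignedSegment] = {}
    second: dict[str, pysam.AlignedSegment] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if not rec.is_paired:
                logger.warning("unpaired record %s dropped", rec.query_name)
                continue
            (first if rec.is_read1 else second)[rec.query_name] = rec

    def oriented(rec: pysam.AlignedSegment) -> tuple[str, tuple[int, ...]]:
        seq = (rec.query_sequence or "").upper()
        qual = tuple(rec.query_qualities) if rec.query_qualities is not None else (40,) * len(seq)
        if rec.is_reverse:
            seq = revcomp(seq)
            qual = qual[::-1]
        return seq, qual

    pairs: list[ReadPair] = []
    for name, r1 in first.items():
        r2 = second.pop(name, None)
        if r2 is None:
            logger.warning("orphan mate for %s dropped", name)
            continue
        if not (r1.is_unmapped and r2.is_unmapped and r1.mate_is_unmapped and r2.mate_is_unmapped):
            continue
        s1, q1 = oriented(r1)
        s2, q2 = oriented(r2)
        pairs.append(ReadPair(pair_id=name, seq1=s1, seq2=s2, qual1=q1, qual2=q2))
    for name in second:
        logger.warning("orphan mate for %s dropped", name)
    return pairs
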