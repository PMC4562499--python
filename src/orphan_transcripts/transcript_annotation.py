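"""Sequence-level characterization of assembled transcripts.

GC-content split (the bimodal-GC / taxonomy contingency analysis), Pearson
chi-square on the 2x4 GC-class x taxon table, PSL (BLAT tabular) ingestion
with best-alignment selection, discontinuous-block (exon/intron) detection,
and a small exact-seed aligner used to place synthetic transcripts on a
proxy-species genome.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from ._seq import revcomp

DEFAULT_GC_CUTOFF = 0.65
DEFAULT_MIN_GAP = 30
TAXA = ("primate", "bacteria", "other_eukaryote", "other")


@dataclass
class AlignmentBlock:
    """One alignment of a transcript to a target sequence (PSL semantics).

    ``blocks`` holds (q_start, q_end, t_start, t_end) per gap-free block,
    sorted and non-overlapping; coordinates 0-based half-open on the + strand
    of the target.
    """

    transcript_id: str
    target_name: str
    strand: str
    q_size: int
    t_size: int
    matches: int
    mismatches: int
    blocks: list[tuple[int, int, int, int]] = field(default_factory=list)

    @property
    def t_start(self) -> int:
        return self.blocks[0][2]

    @property
    def t_end(self) -> int:
        return self.blocks[-1][3]

    @property
    def q_start(self) -> int:
        return self.blocks[0][0]

    @property
    def q_end(self) -> int:
        return self.blocks[-1][1]

    @property
    def identity(self) -> float:
        return self.matches / max(1, self.matches + self.mismatches)

    @property
    def score(self) -> int:
        return self.matches - self.mismatches


def gc_content(seq: str) -> float:
    """(G+C) / (A+C+G+T); N bases excluded entirely."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    acgt = gc + s.count("A") + s.count("T")
    if acgt == 0:
        raise ValueError("sequence contains no called bases")
    return gc / acgt


def split_by_gc(
    transcripts: Mapping[str, str], cutoff: float = DEFAULT_GC_CUTOFF
) -> tuple[set[str], set[str]]:
    """Partition ids into (GC <= cutoff, GC > cutoff)."""
    low = {tid for tid, s in transcripts.items() if gc_content(s) <= cutoff}
    return low, set(transcripts) - low


def taxonomy_chisq(table: Sequence[Sequence[float]]) -> tuple[float, float, int]:
    """Pearson chi-square (no continuity correction) on the 2x4 GC x taxon table."""
    df_table = pd.DataFrame(table)
    if (df_table.sum(axis=0) == 0).any() or (df_table.sum(axis=1) == 0).any():
        raise ValueError("zero marginal: expected counts undefined")
    chi2, p, dof, _ = stats.chi2_contingency(df_table.values, correction=False)
    return float(chi2), float(p), int(dof)


def build_taxonomy_table(
    transcripts: Mapping[str, str],
    taxonomy: Mapping[str, str],
    cutoff: float = DEFAULT_GC_CUTOFF,
) -> pd.DataFrame:
    """2x4 counts: rows GC {<=cutoff, >cutoff}, columns the four taxon classes."""
    low, high = split_by_gc(transcripts, cutoff)
    rows = {"gc_le": low, "gc_gt": high}
    out = pd.DataFrame(0, index=list(rows), columns=list(TAXA))
    for name, ids in rows.items():
        for tid in ids:
            taxon = taxonomy.get(tid, "other")
            if taxon not in TAXA:
                taxon = "other"
            out.loc[name, taxon] += 1
    return out


def is_multiblock(aln: AlignmentBlock, min_gap: int = DEFAULT_MIN_GAP) -> bool:
    """True iff >= 2 blocks with a target-side gap >= min_gap between neighbors.

    Discontinuous target blocks are the signature of exons separated by
    introns absent from the transcript.
    """
    for (_, _, _, t_end), (_, _, t_start, _) in zip(aln.blocks, aln.blocks[1:]):
        if t_start - t_end >= min_gap:
            return True
    return False


def best_alignment(alignments: Iterable[AlignmentBlock]) -> AlignmentBlock | None:
    """Maximal matches-mismatches score; ties by target name then coordinate."""
    ranked = sorted(
        alignments, key=lambda a: (-a.score, a.target_name, a.t_start, a.strand)
    )
    return ranked[0] if ranked else None


def best_alignments_by_transcript(
    alignments: Iterable[AlignmentBlock],
) -> dict[str, AlignmentBlock]:
    grouped: dict[str, list[AlignmentBlock]] = defaultdict(list)
    for a in alignments:
        grouped[a.transcript_id].append(a)
    return {tid: best_alignment(alns) for tid, alns in grouped.items()}


# ---------------------------------------------------------------------------
# PSL (BLAT tabular) reader / writer
# ---------------------------------------------------------------------------

def ingest_psl(path: str | Path) -> list[AlignmentBlock]:
    """Parse a headerless PSL file into alignment records."""
    out: list[AlignmentBlock] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("psLayout", "match", "-", " ")):
                continue
            f = line.split("\t")
            if len(f) != 21:
                raise ValueError(f"{path}:{lineno}: expected 21 PSL fields, got {len(f)}")
            try:
                matches, mismatches = int(f[0]), int(f[1])
                strand, q_name, q_size = f[8], f[9], int(f[10])
                t_name, t_size = f[13], int(f[14])
                n_blocks = int(f[17])
                sizes = [int(x) for x in f[18].rstrip(",").split(",")]
                q_starts = [int(x) for x in f[19].rstrip(",").split(",")]
                t_starts = [int(x) for x in f[20].rstrip(",").split(",")]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed PSL record") from exc
            if not (len(sizes) == len(q_starts) == len(t_starts) == n_blocks):
                raise ValueError(f"{path}:{lineno}: block count mismatch")
            blocks = [
                (qs, qs + sz, ts, ts + sz)
                for sz, qs, ts in zip(sizes, q_starts, t_starts)
            ]
            out.append(
                AlignmentBlock(
                    transcript_id=q_name,
                    target_name=t_name,
                    strand=strand,
                    q_size=q_size,
                    t_size=t_size,
                    matches=matches,
                    mismatches=mismatches,
                    blocks=blocks,
                )
            )
    return out


def write_psl(alignments: Iterable[AlignmentBlock], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in alignments:
            sizes = ",".join(str(qe - qs) for qs, qe, _, _ in a.blocks) + ","
            q_starts = ",".join(str(qs) for qs, _, _, _ in a.blocks) + ","
            t_starts = ",".join(str(ts) for _, _, ts, _ in a.blocks) + ","
            fields = [
                a.matches, a.mismatches, 0, 0, 0, 0, 0, 0,
                a.strand, a.transcript_id, a.q_size, a.q_start, a.q_end,
                a.target_name, a.t_size, a.t_start, a.t_end,
                len(a.blocks), sizes, q_starts, t_starts,
            ]
            fh.write("\t".join(str(x) for x in fields) + "\n")


# ---------------------------------------------------------------------------
# Exact-seed stand-in aligner (synthetic transcripts are exact matches)
# ---------------------------------------------------------------------------

def seed_align(
    transcript_id: str,
    seq: str,
    targets: Mapping[str, str],
    k: int = 28,
) -> list[AlignmentBlock]:
    """Align by chaining exact k-mer anchors on a common diagonal.

    One alignment per (target, strand) with any anchors; blocks are maximal
    runs of diagonal-consistent exact matches.  Adequate for synthetic data
    where transcripts are exact (possibly split) substrings of the target.
    """
    out: list[AlignmentBlock] = []
    for t_name, t_seq in targets.items():
        index: dict[str, list[int]] = defaultdict(list)
        for i in range(len(t_seq) - k + 1):
            index[t_seq[i : i + k]].append(i)
        for strand in ("+", "-"):
            q = seq if strand == "+" else revcomp(seq)
            hits: list[tuple[int, int]] = []  # (q_pos, t_pos)
            for off in range(len(q) - k + 1):
                km = q[off : off + k]
                if "N" in km:
                    continue
                for pos in index.get(km, ()):
                    hits.append((off, pos))
            if not hits:
                continue
            # group anchors by diagonal and merge runs of consecutive offsets
            by_diag: dict[int, list[int]] = defaultdict(list)
            for off, pos in hits:
                by_diag[pos - off].append(off)
            blocks: list[tuple[int, int, int, int]] = []
            for diag, offs in by_diag.items():
                offs.sort()
                run_start = prev = offs[0]
                for o in offs[1:] + [None]:  # type: ignore[list-item]
                    if o is not None and o == prev + 1:
                        prev = o
                        continue
                    qs, qe = run_start, prev + k
                    blocks.append((qs, qe, diag + qs, diag + qe))
                    if o is not None:
                        run_start = prev = o
            blocks.sort()
            # keep non-overlapping blocks in query order
            kept: list[tuple[int, int, int, int]] = []
            for b in blocks:
                if not kept or (b[0] >= kept[-1][1] and b[2] >= kept[-1][3]):
                    kept.append(b)
            matches = sum(qe - qs for qs, qe, _, _ in kept)
            out.append(
                AlignmentBlock(
                    transcript_id=transcript_id,
                    target_name=t_name,
                    strand=strand,
                    q_size=len(seq),
                    t_size=len(t_seq),
                    matches=matches,
                    mismatches=0,
                    blocks=kept,
                )
            )
    return out
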