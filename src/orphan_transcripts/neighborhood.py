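"""Synteny-based nearest-gene assignment and adjacent-gene expression association.

Assembled transcripts absent from the reference genome are placed on a
better-assembled proxy species (chimp/gorilla analog); the nearest annotated
gene there is carried through a one-to-one homolog map back to the target
species.  The neighborhood-conservation statistic quantifies how often a
gene's nearest neighbor is preserved (via homology) between the two
annotations, and the adjacent-gene association asks whether the neighbor's
expression differs between samples that do and do not express the transcript,
separately within cancer and normal strata.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .expression_quant import DEFAULT_ALPHA, ExpressionMatrix, rank_sum_test
from .transcript_annotation import AlignmentBlock, best_alignment

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Feature:
    chrom: str
    start: int
    end: int
    name: str
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"invalid interval for {self.name}: [{self.start}, {self.end})")


@dataclass
class FeatureSet:
    """Named intervals (0-based half-open, BED convention) for one species."""

    species: str
    features: list[Feature] = field(default_factory=list)
    _by_chrom: dict[str, list[Feature]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        if len(names) != len(set(names)):
            raise ValueError("feature ids must be unique within a species")
        by_chrom: dict[str, list[Feature]] = {}
        for f in self.features:
            by_chrom.setdefault(f.chrom, []).append(f)
        for fs in by_chrom.values():
            fs.sort(key=lambda f: (f.start, f.end, f.name))
        self._by_chrom = by_chrom

    def by_name(self) -> dict[str, Feature]:
        return {f.name: f for f in self.features}

    @classmethod
    def from_bed(cls, path: str | Path, species: str) -> "FeatureSet":
        df = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "start", "end", "name", "score", "strand"],
        )
        feats = [
            Feature(r.chrom, int(r.start), int(r.end), str(r.name), str(r.strand))
            for r in df.itertuples()
        ]
        return cls(species=species, features=feats)

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for f in sorted(self.features, key=lambda f: (f.chrom, f.start)):
                fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.name}\t0\t{f.strand}\n")


def _interval_distance(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Gap between two half-open intervals; 0 when they overlap."""
    return max(0, max(a_start, b_start) - min(a_end, b_end))


def nearest_feature(
    features: FeatureSet,
    chrom: str,
    start: int,
    end: int,
    exclude: str | None = None,
) -> tuple[str | None, int | None]:
    """Closest feature on the query's sequence; ties go to the smaller start.

    Distance is the gap between the closest interval ends (0 on overlap);
    strand is ignored, as in bedtools closest defaults.
    """
    feats = features._by_chrom.get(chrom, [])
    if exclude is not None:
        feats = [f for f in feats if f.name != exclude]
    if not feats:
        return None, None
    starts = [f.start for f in feats]
    max_len = max(f.end - f.start for f in feats)
    i = bisect.bisect_left(starts, start)
    best: tuple[int, int, str] | None = None

    def consider(f: Feature) -> None:
        nonlocal best
        key = (_interval_distance(start, end, f.start, f.end), f.start, f.name)
        if best is None or key < best:
            best = key

    # rightwards: starts are sorted, so distance grows monotonically
    for f in feats[i:]:
        if best is not None and f.start - end > best[0]:
            break
        consider(f)
    # leftwards: a feature can still be close if long; bound via max_len
    for f in reversed(feats[:i]):
        if best is not None and start - (f.start + max_len) > best[0]:
            break
        consider(f)
    return best[2], best[0]


@dataclass
class HomologMap:
    """One-to-one gene id pairing between two species."""

    pairs: dict[str, str]

    def __post_init__(self) -> None:
        values = list(self.pairs.values())
        if len(values) != len(set(values)):
            raise ValueError("homolog map must be one-to-one")

    def get(self, gene: str) -> str | None:
        return self.pairs.get(gene)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "HomologMap":
        df = pd.read_csv(path, sep="\t")
        return cls(pairs=dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str))))

    def to_tsv(self, path: str | Path, col_a: str = "proxy_gene", col_b: str = "human_gene") -> None:
        with open(path, "w") as fh:
            fh.write(f"{col_a}\t{col_b}\n")
            for a, b in sorted(self.pairs.items()):
                fh.write(f"{a}\t{b}\n")


def assign_adjacent_gene(
    alignments: Iterable[AlignmentBlock],
    annotations: Mapping[str, FeatureSet],
    homologs: Mapping[str, HomologMap],
) -> dict[str, str | None]:
    """Map each transcript to the human homolog of its nearest proxy gene.

    When alignments exist in several proxy species the one with the higher
    best-alignment score wins.  Transcripts with no alignment, no neighbor or
    no homolog are unassigned (None), logged.
    """
    per_transcript: dict[str, list[tuple[str, AlignmentBlock]]] = {}
    chrom_to_species = {
        f.chrom: sp for sp, fs in annotations.items() for f in fs.features
    }
    for a in alignments:
        sp = chrom_to_species.get(a.target_name)
        if sp is None:
            continue
        per_transcript.setdefault(a.transcript_id, []).append((sp, a))
    out: dict[str, str | None] = {}
    for tid, cands in per_transcript.items():
        ranked = sorted(
            (
                (sp, best_alignment([a for s, a in cands if s == sp]))
                for sp in {s for s, _ in cands}
            ),
            key=lambda x: (-x[1].score, x[0]),
        )
        assigned = None
        for sp, aln in ranked:
            gene, _ = nearest_feature(annotations[sp], aln.target_name, aln.t_start, aln.t_end)
            if gene is None:
                continue
            human = homologs[sp].get(gene)
            if human is None:
                logger.info("transcript %s: nearest gene %s has no homolog", tid, gene)
                continue
            assigned = human
            break
        if assigned is None:
            logger.info("transcript %s unassigned", tid)
        out[tid] = assigned
    return out


def neighborhood_conservation(
    annot_a: FeatureSet,
    annot_b: FeatureSet,
    homologs: HomologMap,
) -> float:
    """Fraction of genes whose nearest neighbor is conserved across species.

    For each gene of A with a homolog present in B: its nearest neighbor in A,
    mapped through the homolog table, must equal the nearest neighbor of its
    homolog in B.  Genes without a mappable comparison are excluded from the
    denominator (logged).
    """
    if not homologs.pairs:
        raise ValueError("empty homolog map: conservation undefined")
    b_names = set(annot_b.by_name())
    total = conserved = 0
    for f in annot_a.features:
        hb = homologs.get(f.name)
        if hb is None or hb not in b_names:
            logger.info("gene %s absent in B; excluded", f.name)
            continue
        nn_a, _ = nearest_feature(annot_a, f.chrom, f.start, f.end, exclude=f.name)
        if nn_a is None:
            continue
        fb = annot_b.by_name()[hb]
        nn_b, _ = nearest_feature(annot_b, fb.chrom, fb.start, fb.end, exclude=fb.name)
        if nn_b is None:
            continue
        total += 1
        if homologs.get(nn_a) == nn_b:
            conserved += 1
    if total == 0:
        raise ValueError("no comparable genes: conservation undefined")
    return conserved / total


def adjacent_gene_association(
    gene_matrix: ExpressionMatrix,
    transcript_matrix: ExpressionMatrix,
    assignment: Mapping[str, str | None],
    alpha: float = DEFAULT_ALPHA,
    min_group: int = 3,
    positive_threshold: float = 0.0,
) -> dict[str, str]:
    """Category per transcript: cancer_only, normal_only, both or none.

    Within each condition stratum, the adjacent gene's expression in samples
    expressing the transcript is compared against non-expressing samples by
    the two-sided rank-sum test; a stratum needs >= min_group samples per
    group to be tested.
    """
    out: dict[str, str] = {}
    meta = transcript_matrix.meta
    for tid, gene in assignment.items():
        if gene is None or gene not in gene_matrix.values.index:
            out[tid] = "none"
            continue
        expressing = transcript_matrix.values.loc[tid] > positive_threshold
        sig = {}
        for cond in ("cancer", "normal"):
            samples = meta.index[meta["condition"] == cond]
            samples = [s for s in samples if s in gene_matrix.values.columns]
            pos = [s for s in samples if expressing.get(s, False)]
            neg = [s for s in samples if not expressing.get(s, False)]
            if len(pos) < min_group or len(neg) < min_group:
                logger.info("transcript %s %s stratum untested (groups %d/%d)", tid, cond, len(pos), len(neg))
                sig[cond] = False
                continue
            p = rank_sum_test(
                gene_matrix.values.loc[gene, pos].tolist(),
                gene_matrix.values.loc[gene, neg].tolist(),
            )
            sig[cond] = p <= alpha
        if sig.get("cancer") and sig.get("normal"):
            out[tid] = "both"
        elif sig.get("cancer"):
            out[tid] = "cancer_only"
        elif sig.get("normal"):
            out[tid] = "normal_only"
        else:
            out[tid] = "none"
    return out
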