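"""RPKM quantification and the frequent / cancer-associated classification.

Expression of an assembled transcript in a sample is RPKM = (1e9 * C)/(N * L)
with C the uniquely mapped high-quality read count, N the library's unique
high-quality read count and L the transcript length.  A transcript is
"expressed" in a sample when RPKM exceeds a positive threshold (default 0,
i.e. any uniquely mapped read), and "frequently expressed" when it is
expressed in more than 10% of same-tissue samples.  Frequent transcripts are
then tested per tissue for a cancer-vs-normal difference in expression
frequency with a two-sided Fisher exact test (Bonferroni across tissues) and
labelled cancer_up / normal_up / mixed / similar; a rank-sum statistic over
per-tissue frequencies is reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import comb, sqrt
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assembly_join import Transcript, TranscriptIndex
from .read_screening import ReadPair

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 1e-4
DEFAULT_FREQ_CUTOFF = 0.10
DEFAULT_MAX_TISSUES = 3
CONDITIONS = ("cancer", "normal")


@dataclass
class ExpressionMatrix:
    """Transcripts x samples RPKM with sample metadata.

    ``meta`` is indexed by sample id with columns ``tissue`` and ``condition``
    (cancer|normal); ``lengths`` and ``lib_sizes`` carry L and N.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    lengths: pd.Series
    lib_sizes: pd.Series

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("RPKM values must be non-negative")
        missing = set(self.values.columns) - set(self.meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")
        bad = set(self.meta["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown conditions: {bad}")

    def write(self, matrix_path: str | Path, meta_path: str | Path) -> None:
        self.values.to_csv(matrix_path, sep="\t", index_label="transcript")
        self.meta.to_csv(meta_path, sep="\t", index_label="sample")

    @classmethod
    def read(
        cls,
        matrix_path: str | Path,
        meta_path: str | Path,
        lengths: pd.Series | None = None,
        lib_sizes: pd.Series | None = None,
    ) -> "ExpressionMatrix":
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        if lengths is None:
            lengths = pd.Series(1000, index=values.index)
        if lib_sizes is None:
            lib_sizes = pd.Series(1_000_000, index=values.columns)
        return cls(values=values, meta=meta, lengths=lengths, lib_sizes=lib_sizes)


@dataclass
class AssociationResult:
    transcript: str
    per_tissue: dict[str, dict] = field(default_factory=dict)
    global_p: float = 1.0
    ranksum_p: float | None = None
    category: str = "similar"
    tissue_specific: bool = False


def rpkm(c: float, n: float, length: float) -> float:
    """Reads per kilobase of transcript per million library reads."""
    if n <= 0 or length <= 0:
        raise ValueError("library size N and length L must be positive")
    if c < 0:
        raise ValueError("read count C must be non-negative")
    return (1e9 * c) / (n * length)


def quantify(
    pairs: Sequence[ReadPair],
    transcripts: Sequence[Transcript],
    k: int = 28,
) -> pd.Series:
    """One library's RPKM column over a transcript set.

    C counts mates with a unique best exact-seed placement on the transcript
    (ambiguous placements count for nothing); N is twice the retained pair
    count (every mate is a read).
    """
    index = TranscriptIndex(transcripts, k=k)
    counts = {t.id: 0 for t in transcripts}
    for p in pairs:
        for seq in (p.seq1, p.seq2):
            placed = index.place(seq)
            if placed is not None:
                counts[placed[0]] += 1
    n_reads = 2 * len(pairs)
    lengths = {t.id: len(t.seq) for t in transcripts}
    return pd.Series(
        {
            tid: rpkm(c, n_reads, lengths[tid]) if n_reads else 0.0
            for tid, c in counts.items()
        }
    )


def expression_frequency(
    matrix: ExpressionMatrix, positive_threshold: float = 0.0
) -> pd.DataFrame:
    """Per transcript x tissue x condition: expressing count, total, frequency."""
    expressed = matrix.values > positive_threshold
    records = []
    for (tissue, condition), samples in matrix.meta.groupby(
        ["tissue", "condition"], sort=True
    ).groups.items():
        cols = [s for s in samples if s in expressed.columns]
        if not cols:
            logger.warning("tissue %s/%s has no samples", tissue, condition)
            continue
        n_exp = expressed[cols].sum(axis=1)
        for tid, ne in n_exp.items():
            records.append(
                {
                    "transcript": tid,
                    "tissue": tissue,
                    "condition": condition,
                    "n_expressing": int(ne),
                    "n_total": len(cols),
                    "frequency": ne / len(cols),
                }
            )
    return pd.DataFrame.from_records(
        records, columns=["transcript", "tissue", "condition", "n_expressing", "n_total", "frequency"]
    )


def classify_frequent(
    records: pd.DataFrame, freq_cutoff: float = DEFAULT_FREQ_CUTOFF
) -> set[str]:
    """Frequent iff frequency strictly exceeds the cutoff in any tissue x condition."""
    if records.empty:
        return set()
    hit = records[records["frequency"] > freq_cutoff]
    return set(hit["transcript"])


def frequent_tissues(
    records: pd.DataFrame, freq_cutoff: float = DEFAULT_FREQ_CUTOFF
) -> dict[str, set[str]]:
    """Tissues in which each transcript is frequently expressed."""
    out: dict[str, set[str]] = {}
    if records.empty:
        return out
    for _, row in records[records["frequency"] > freq_cutoff].iterrows():
        out.setdefault(row["transcript"], set()).add(row["tissue"])
    return out


# ---------------------------------------------------------------------------
# Exact tests
# ---------------------------------------------------------------------------

def fisher_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p by exact integer hypergeometric enumeration.

    p = sum of the probabilities of all tables (at the observed margins) no
    more probable than the observed one.  Degenerate margins give p = 1.
    """
    (a, b), (c, d) = table
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("table entries must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    row1, col1 = a + b, a + c
    if n == 0 or row1 in (0, n) or col1 in (0, n):
        return 1.0
    kmin, kmax = max(0, row1 + col1 - n), min(row1, col1)
    weights = [comb(col1, k) * comb(n - col1, row1 - k) for k in range(kmin, kmax + 1)]
    obs = weights[a - kmin]
    return sum(w for w in weights if w <= obs) / comb(n, row1)


def _midranks_doubled(values: Sequence[float]) -> list[int]:
    """Mid-ranks times two (integers even under ties), in input order."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    doubled = [0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        r2 = (i + 1) + (j + 1)  # 2 * average rank
        for idx in order[i : j + 1]:
            doubled[idx] = r2
        i = j + 1
    return doubled


def rank_sum_test(x: Sequence[float], y: Sequence[float], exact_max_n: int = 12) -> float:
    """Two-sided rank-sum test for two independent groups.

    Exact permutation distribution (mid-rank ties, integer arithmetic on
    doubled ranks) when the pooled size is <= ``exact_max_n``; otherwise a
    tie-corrected normal approximation.  All values identical gives p = 1.
    """
    x, y = list(x), list(y)
    if not x or not y:
        raise ValueError("both groups must be non-empty")
    pooled = x + y
    if len(set(pooled)) == 1:
        return 1.0
    nx, n = len(x), len(pooled)
    d2 = _midranks_doubled(pooled)
    w_obs2 = sum(d2[:nx])
    mean2 = nx * (n + 1)  # 2 * E[W]
    dev_obs = abs(w_obs2 - mean2)
    if n <= exact_max_n:
        hits = sum(
            1
            for idx in combinations(range(n), nx)
            if abs(sum(d2[i] for i in idx) - mean2) >= dev_obs
        )
        return hits / comb(n, nx)
    ny = n - nx
    ties = pd.Series(pooled).value_counts().to_numpy()
    tie_term = float(((ties**3 - ties).sum())) / (n * (n - 1))
    var = nx * ny / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    z = (dev_obs / 2.0) / sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(z)))


# ---------------------------------------------------------------------------
# Cancer / normal association
# ---------------------------------------------------------------------------

def classify_association(
    frequent: Iterable[str],
    matrix: ExpressionMatrix,
    alpha: float = DEFAULT_ALPHA,
    freq_cutoff: float = DEFAULT_FREQ_CUTOFF,
    max_tissues: int = DEFAULT_MAX_TISSUES,
    positive_threshold: float = 0.0,
) -> list[AssociationResult]:
    """Label each frequent transcript by its cancer/normal frequency contrast.

    Per tissue with both conditions present, a 2x2 (expressing x condition)
    Fisher test; a tissue is significant when its p times the number of
    tested tissues (Bonferroni) is <= alpha.  Category: cancer_up if every
    significant tissue favors cancer, normal_up if every one favors normal,
    mixed when both directions occur, similar when none is significant.
    The tissue_specific flag marks similar transcripts frequent in at most
    ``max_tissues`` tissues.
    """
    frequent = sorted(set(frequent))
    expressed = matrix.values > positive_threshold
    tissue_masks: dict[str, dict[str, np.ndarray]] = {}
    for tissue, sub in matrix.meta.groupby("tissue", sort=True):
        masks = {}
        for cond in CONDITIONS:
            ids = sub.index[sub["condition"] == cond]
            masks[cond] = expressed.columns.isin(ids)
        if masks["cancer"].any() and masks["normal"].any():
            tissue_masks[tissue] = masks
        else:
            logger.info("tissue %s lacks one condition; excluded from testing", tissue)
    n_tissues = max(1, len(tissue_masks))

    freq_rec = expression_frequency(matrix, positive_threshold)
    freq_by_tissue = frequent_tissues(freq_rec, freq_cutoff)

    exp_values = expressed.values
    col_count = {t: {c: int(m.sum()) for c, m in masks.items()} for t, masks in tissue_masks.items()}
    row_index = {tid: i for i, tid in enumerate(matrix.values.index)}

    results: list[AssociationResult] = []
    for tid in frequent:
        i = row_index[tid]
        res = AssociationResult(transcript=tid)
        directions: set[str] = set()
        best_p = 1.0
        freq_c, freq_n = [], []
        for tissue, masks in tissue_masks.items():
            e_can = int(exp_values[i, masks["cancer"]].sum())
            e_nor = int(exp_values[i, masks["normal"]].sum())
            n_can, n_nor = col_count[tissue]["cancer"], col_count[tissue]["normal"]
            table = [[e_can, n_can - e_can], [e_nor, n_nor - e_nor]]
            p = fisher_2x2(table)
            f_can, f_nor = e_can / n_can, e_nor / n_nor
            direction = "cancer" if f_can > f_nor else ("normal" if f_nor > f_can else "equal")
            res.per_tissue[tissue] = {"table": table, "p": p, "direction": direction}
            best_p = min(best_p, p)
            freq_c.append(f_can)
            freq_n.append(f_nor)
            if p * n_tissues <= alpha and direction != "equal":
                directions.add(direction)
        res.global_p = min(1.0, best_p * n_tissues)
        if len(freq_c) >= 2:
            res.ranksum_p = rank_sum_test(freq_c, freq_n)
        if directions == {"cancer"}:
            res.category = "cancer_up"
        elif directions == {"normal"}:
            res.category = "normal_up"
        elif len(directions) == 2:
            res.category = "mixed"
        else:
            res.category = "similar"
            res.tissue_specific = len(freq_by_tissue.get(tid, ())) <= max_tissues
        results.append(res)
    return results


def association_table(results: Iterable[AssociationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "transcript": r.transcript,
                "category": r.category,
                "global_p": r.global_p,
                "ranksum_p": r.ranksum_p,
                "tissue_specific": r.tissue_specific,
            }
        )
    return pd.DataFrame(rows)
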