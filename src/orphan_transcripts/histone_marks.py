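"""Poisson enrichment calling of histone marks on off-reference transcripts.

For each transcript x cell line x mark, the treatment (ChIP) signal x and the
control (input) signal lambda are RPKM values computed over the transcript's
*effective length* — the part of the transcript covered by at least one read
in any histone-mark library.  Significance is the Poisson upper tail
1 - F_Poisson(x; lambda); because RPKM is real-valued the tail is evaluated
through its regularized lower incomplete gamma continuation (which equals the
exact tail sum at integer x), with an optional integer-floor mode.  Calls at
P <= 1e-4 are classified into H3K4me3-only / H3K27ac-only / both / none
patterns, and matching between mark tissue and frequent-expression tissue is
scored by a Fisher exact test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import special

from .expression_quant import fisher_2x2, rpkm

logger = logging.getLogger(__name__)

MARKS = ("H3K4me3", "H3K27ac")
DEFAULT_CUTOFF = 1e-4


@dataclass
class HistoneSignal:
    transcript: str
    cell_line: str
    mark: str
    treatment_count: int
    control_count: int
    n_treatment: int
    n_control: int
    effective_length: int
    x: float | None = None
    lam: float | None = None
    p_value: float | None = None


@dataclass(frozen=True)
class MarkCall:
    transcript: str
    cell_line: str
    pattern: str  # K4_only | K27_only | both | none
    p_values: tuple[tuple[str, float], ...]


def effective_length(coverages: Sequence[Sequence[int]]) -> int:
    """Positions covered by >= 1 read in the union of all mark libraries."""
    if not coverages:
        raise ValueError("effective_length requires at least one coverage vector")
    arr = np.asarray(coverages)
    if arr.ndim != 2 or len({len(c) for c in coverages}) != 1:
        raise ValueError("coverage vectors must have equal length")
    return int((arr.sum(axis=0) > 0).sum())


def poisson_tail(x: float, lam: float) -> float:
    """P(X >= x) for X ~ Poisson(lam), continuously extended in x.

    The regularized lower incomplete gamma P(x, lam) equals the exact tail
    sum for integer x >= 1; x = 0 gives 1 by convention.
    """
    if x < 0 or lam < 0:
        raise ValueError("x and lambda must be non-negative")
    if x == 0:
        return 1.0
    if lam == 0:
        return 0.0
    return float(special.gammainc(x, lam))


def score_signal(sig: HistoneSignal, floor_x: bool = False) -> HistoneSignal:
    """Fill x, lambda (RPKM over the effective length) and the Poisson p-value.

    A transcript with zero effective length (no coverage anywhere) carries no
    evidence: p = 1.
    """
    if sig.effective_length <= 0:
        sig.x, sig.lam, sig.p_value = 0.0, 0.0, 1.0
        return sig
    sig.x = rpkm(sig.treatment_count, sig.n_treatment, sig.effective_length)
    sig.lam = rpkm(sig.control_count, sig.n_control, sig.effective_length)
    if floor_x:
        sig.x = float(math.floor(sig.x))
    sig.p_value = poisson_tail(sig.x, sig.lam)
    return sig


def call_marks(
    signals: Iterable[HistoneSignal],
    cutoff: float = DEFAULT_CUTOFF,
    floor_x: bool = False,
) -> list[MarkCall]:
    """Per transcript x cell line, assemble the mark pattern at P <= cutoff."""
    grouped: dict[tuple[str, str], dict[str, float]] = {}
    for sig in signals:
        if sig.p_value is None:
            score_signal(sig, floor_x=floor_x)
        grouped.setdefault((sig.transcript, sig.cell_line), {})[sig.mark] = sig.p_value
    calls = []
    for (tid, cl), ps in sorted(grouped.items()):
        for mark in MARKS:
            if mark not in ps:
                logger.info("%s/%s: mark %s missing, treated as not significant", tid, cl, mark)
        k4 = ps.get("H3K4me3", 1.0) <= cutoff
        k27 = ps.get("H3K27ac", 1.0) <= cutoff
        pattern = {(True, True): "both", (True, False): "K4_only",
                   (False, True): "K27_only", (False, False): "none"}[(k4, k27)]
        calls.append(MarkCall(tid, cl, pattern, tuple(sorted(ps.items()))))
    return calls


def tissue_match_enrichment(
    calls: Iterable[MarkCall],
    frequent_tissues: Mapping[str, set[str]],
    cell_line_tissue: Mapping[str, str],
) -> tuple[list[list[int]], float]:
    """2x2 over (transcript, tissue) units: significant mark in a cell line of
    that tissue, crossed with frequent expression in that tissue; Fisher p.
    """
    marked: dict[str, set[str]] = {}
    transcripts: set[str] = set()
    tissues: set[str] = set(cell_line_tissue.values())
    for c in calls:
        if c.cell_line not in cell_line_tissue:
            raise ValueError(f"cell line {c.cell_line} has no tissue mapping")
        transcripts.add(c.transcript)
        if c.pattern != "none":
            marked.setdefault(c.transcript, set()).add(cell_line_tissue[c.cell_line])
    table = [[0, 0], [0, 0]]
    for tid in sorted(transcripts):
        for tissue in sorted(tissues):
            has_mark = tissue in marked.get(tid, ())
            is_freq = tissue in frequent_tissues.get(tid, ())
            table[0 if has_mark else 1][0 if is_freq else 1] += 1
    return table, fisher_2x2(table)
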