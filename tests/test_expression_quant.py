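"""RPKM, exact tests, and the cancer/normal frequency classification."""

from fractions import Fraction
from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from orphan_transcripts import (
    ExpressionMatrix,
    ReadPair,
    Transcript,
    classify_association,
    classify_frequent,
    expression_frequency,
    fisher_2x2,
    quantify,
    rank_sum_test,
    rpkm,
)
from orphan_transcripts._seq import revcomp


class TestRpkm:
    def test_direct_substitution(self):
        assert rpkm(50, 2e7, 500) == 5.0
        assert rpkm(0, 1e6, 100) == 0.0

    def test_doubling_library_halves_rpkm(self):
        assert rpkm(7, 2e6, 333) == pytest.approx(rpkm(7, 1e6, 333) / 2)

    def test_invalid_inputs(self):
        for args in [(1, 0, 100), (1, 100, 0), (-1, 100, 100)]:
            with pytest.raises(ValueError):
                rpkm(*args)


def _matrix(values, meta_rows):
    samples = list(values.columns)
    meta = pd.DataFrame(meta_rows, index=samples, columns=["tissue", "condition"])
    return ExpressionMatrix(
        values=values, meta=meta,
        lengths=pd.Series(500, index=values.index),
        lib_sizes=pd.Series(1e6, index=samples),
    )


class TestQuantify:
    def setup_method(self):
        import random

        rng = random.Random(8)
        self.t1 = Transcript(id="a", seq="".join(rng.choice("ACGT") for _ in range(500)))
        self.t2 = Transcript(id="b", seq="".join(rng.choice("ACGT") for _ in range(500)))

    def pairs_from(self, seq, n, read_len=100):
        out = []
        for i in range(n):
            s = (i * 37) % (len(seq) - 2 * read_len)
            out.append(ReadPair(f"p{i}", seq[s : s + read_len],
                                revcomp(seq[s + read_len : s + 2 * read_len]),
                                (40,) * read_len, (40,) * read_len))
        return out

    def test_untouched_transcript_has_zero_rpkm(self):
        col = quantify(self.pairs_from(self.t1.seq, 10), [self.t1, self.t2])
        assert col["b"] == 0.0 and col["a"] > 0

    def test_counts_track_read_numbers(self):
        pairs = self.pairs_from(self.t1.seq, 10)
        col = quantify(pairs, [self.t1])
        # 20 mates uniquely placed: RPKM = 1e9 * 20 / (20 * 500)
        assert col["a"] == pytest.approx(1e9 * 20 / (20 * 500))

    def test_ambiguous_read_counts_for_neither(self):
        twin = Transcript(id="a2", seq=self.t1.seq)
        col = quantify(self.pairs_from(self.t1.seq, 5), [self.t1, twin])
        assert col["a"] == 0.0 and col["a2"] == 0.0


class TestExpressionFrequency:
    def test_counts_and_threshold_monotonicity(self):
        values = pd.DataFrame(
            {"s1": [0.0, 5.0], "s2": [0.0, 0.5], "s3": [0.0, 0.0]},
            index=["t_zero", "t_some"],
        )
        m = _matrix(values, [("lung", "cancer")] * 3)
        rec = expression_frequency(m)
        zero = rec[rec.transcript == "t_zero"]
        assert (zero.frequency == 0).all()
        some = rec[rec.transcript == "t_some"].iloc[0]
        assert some.n_expressing == 2 and some.frequency == pytest.approx(2 / 3)
        rec_hi = expression_frequency(m, positive_threshold=10.0)
        assert (rec_hi.frequency == 0).all()

    def test_frequent_threshold_is_strict(self):
        rec = pd.DataFrame(
            [
                {"transcript": "t15", "tissue": "x", "condition": "cancer", "n_expressing": 3, "n_total": 20, "frequency": 0.15},
                {"transcript": "t10", "tissue": "x", "condition": "cancer", "n_expressing": 2, "n_total": 20, "frequency": 0.10},
                {"transcript": "t0", "tissue": "x", "condition": "cancer", "n_expressing": 0, "n_total": 20, "frequency": 0.0},
            ]
        )
        assert classify_frequent(rec, freq_cutoff=0.10) == {"t15"}


def fisher_oracle(a, b, c, d):
    """Independent brute force: exact rational hypergeometric enumeration."""

    def hyper(k, row1, col1, n):
        return (
            Fraction(factorial(row1) * factorial(n - row1) * factorial(col1) * factorial(n - col1),
                     factorial(n))
            / (factorial(k) * factorial(row1 - k) * factorial(col1 - k) * factorial(n - row1 - col1 + k))
        )

    n, row1, col1 = a + b + c + d, a + b, a + c
    if n == 0 or row1 in (0, n) or col1 in (0, n):
        return 1.0
    obs = hyper(a, row1, col1, n)
    total = Fraction(0)
    for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        pk = hyper(k, row1, col1, n)
        if pk <= obs:
            total += pk
    return float(total)


class TestFisher:
    def test_derived_example(self):
        assert fisher_2x2([[8, 2], [2, 8]]) == pytest.approx(0.023014, abs=1e-6)

    def test_balanced_table_is_null(self):
        assert fisher_2x2([[5, 5], [5, 5]]) == 1.0

    def test_degenerate_margins(self):
        assert fisher_2x2([[0, 0], [3, 4]]) == 1.0
        assert fisher_2x2([[2, 0], [3, 0]]) == 1.0

    def test_row_swap_symmetry(self):
        assert fisher_2x2([[8, 2], [2, 8]]) == fisher_2x2([[2, 8], [8, 2]])

    def test_rejects_non_integers(self):
        with pytest.raises(ValueError):
            fisher_2x2([[1.5, 2], [3, 4]])

    def test_matches_exact_enumeration_oracle_small_tables(self):
        for a in range(5):
            for b in range(5):
                for c in range(5):
                    for d in range(5):
                        assert fisher_2x2([[a, b], [c, d]]) == fisher_oracle(a, b, c, d)

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            t = rng.integers(0, 30, size=(2, 2))
            ours = fisher_2x2(t.tolist())
            theirs = stats.fisher_exact(t)[1]
            assert ours == pytest.approx(theirs, rel=1e-9, abs=1e-12)


def ranksum_oracle(x, y):
    """Independent enumeration with Fraction mid-ranks."""
    pooled = x + y
    if len(set(pooled)) == 1:
        return 1.0
    srt = sorted(pooled)
    rank = {}
    i = 0
    while i < len(srt):
        j = i
        while j + 1 < len(srt) and srt[j + 1] == srt[i]:
            j += 1
        for v in {srt[i]}:
            rank[v] = Fraction(i + 1 + j + 1, 2)
        i = j + 1
    ranks = [rank[v] for v in pooled]
    nx, n = len(x), len(pooled)
    mean = Fraction(nx * (n + 1), 2)
    obs = abs(sum(ranks[:nx]) - mean)
    hits = sum(
        1 for idx in combinations(range(n), nx)
        if abs(sum(ranks[i] for i in idx) - mean) >= obs
    )
    from math import comb

    return hits / comb(n, nx)


class TestRankSum:
    def test_exact_example(self):
        assert rank_sum_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_groups(self):
        assert rank_sum_test([2, 2, 2], [2, 2, 2]) == 1.0
        assert rank_sum_test([1, 3, 2], [2, 1, 3]) == 1.0

    def test_group_swap_symmetry(self):
        x, y = [1.2, 5.5, 3.0], [2.2, 8.8]
        assert rank_sum_test(x, y) == rank_sum_test(y, x)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])

    def test_matches_enumeration_oracle_with_ties(self):
        rng = np.random.default_rng(1)
        for _ in range(40):
            nx, ny = int(rng.integers(1, 6)), int(rng.integers(1, 6))
            vals = rng.integers(0, 4, size=nx + ny).tolist()  # heavy ties
            x, y = vals[:nx], vals[nx:]
            assert rank_sum_test(x, y) == ranksum_oracle(x, y)

    def test_large_sample_normal_tail_is_sane(self):
        x = list(range(50))
        y = [v + 30 for v in range(50)]
        p = rank_sum_test(x, y)
        assert 0 < p < 1e-10


def planted_matrix(n_per_cell, rates, tissues=("T1",), seed=0, n_null=0, null_rate=0.3):
    """rates: {(tissue, condition): p} for the single planted transcript."""
    rng = np.random.default_rng(seed)
    cols, meta_rows = [], []
    for t in tissues:
        for cond in ("cancer", "normal"):
            for i in range(n_per_cell):
                cols.append(f"{t}_{cond}_{i}")
                meta_rows.append((t, cond))
    data = {}
    row = []
    for t, cond in meta_rows:
        row.append(rates.get((t, cond), 0.0))
    data["planted"] = (rng.random(len(cols)) < np.array(row)) * 5.0
    for k in range(n_null):
        data[f"null_{k}"] = (rng.random(len(cols)) < null_rate) * 5.0
    values = pd.DataFrame(data, index=cols).T
    return _matrix(values, meta_rows)


class TestClassifyAssociation:
    def test_planted_cancer_up_is_recovered(self):
        m = planted_matrix(200, {("T1", "cancer"): 0.5, ("T1", "normal"): 0.05}, seed=3)
        res = classify_association(["planted"], m)[0]
        assert res.category == "cancer_up" and res.global_p < 1e-4

    def test_planted_normal_up_is_recovered(self):
        m = planted_matrix(200, {("T1", "cancer"): 0.05, ("T1", "normal"): 0.5}, seed=4)
        assert classify_association(["planted"], m)[0].category == "normal_up"

    def test_opposite_tissues_are_mixed(self):
        m = planted_matrix(
            200,
            {("T1", "cancer"): 0.6, ("T1", "normal"): 0.05,
             ("T2", "cancer"): 0.05, ("T2", "normal"): 0.6},
            tissues=("T1", "T2"), seed=5,
        )
        assert classify_association(["planted"], m)[0].category == "mixed"

    def test_equal_rates_are_similar_and_tissue_specific(self):
        m = planted_matrix(100, {("T1", "cancer"): 0.4, ("T1", "normal"): 0.4}, seed=6)
        res = classify_association(["planted"], m)[0]
        assert res.category == "similar" and res.tissue_specific

    def test_classification_invariant_under_sample_permutation(self):
        m = planted_matrix(60, {("T1", "cancer"): 0.5, ("T1", "normal"): 0.05}, seed=7)
        rng = np.random.default_rng(0)
        perm = rng.permutation(m.values.columns)
        m2 = ExpressionMatrix(values=m.values[perm], meta=m.meta.loc[perm],
                              lengths=m.lengths, lib_sizes=m.lib_sizes.loc[perm])
        r1 = classify_association(["planted"], m)[0]
        r2 = classify_association(["planted"], m2)[0]
        assert (r1.category, r1.global_p) == (r2.category, r2.global_p)
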