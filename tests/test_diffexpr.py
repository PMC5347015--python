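"""The exact two-library test, FDR control, and DEG set operations.

Oracles: an exact rational-arithmetic evaluation of the conditional pmf and
its tails (stdlib fractions), the identity that the conditional law of y
given x is negative binomial NB(x+1, N1/(N1+N2)), and a naive double-loop
step-up for the FDR adjustment.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import nbinom

from chillseq.diffexpr import (
    ContrastTable,
    GeneDEResult,
    GenePairObs,
    ac_log_pmf,
    ac_two_sided_p,
    bh_fdr,
    log2_ratio,
    opposite_direction,
    run_contrast,
    shared_degs,
    venn_counts,
)
from chillseq.model import ChillseqError, CountMatrix, DEGThresholds


def pmf_exact(y: int, x: int, n1: int, n2: int) -> Fraction:
    r = Fraction(n2, n1)
    return (
        r**y
        * Fraction(math.factorial(x + y), math.factorial(x) * math.factorial(y))
        / (1 + r) ** (x + y + 1)
    )


def two_sided_exact(x: int, y: int, n1: int, n2: int) -> Fraction:
    lower = sum(pmf_exact(yy, x, n1, n2) for yy in range(y + 1))
    upper = 1 - lower + pmf_exact(y, x, n1, n2)
    return min(Fraction(1), 2 * min(lower, upper))


class TestPmf:
    def test_double_zero_equal_libraries_is_half(self):
        assert ac_log_pmf(0, 0, 10**6, 10**6) == pytest.approx(math.log(0.5))

    def test_one_one_equal_libraries(self):
        assert ac_log_pmf(1, 1, 500, 500) == pytest.approx(math.log(0.25))

    def test_against_rational_oracle_unequal_libraries(self):
        expected = pmf_exact(20, 5, 10**4, 2 * 10**4)
        got = math.exp(ac_log_pmf(20, 5, 10**4, 2 * 10**4))
        assert got == pytest.approx(float(expected), rel=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ChillseqError):
            ac_log_pmf(-1, 0, 10, 10)

    @given(
        x=st.integers(0, 60),
        y=st.integers(0, 60),
        n1=st.sampled_from([10**4, 10**5, 10**6]),
        ratio=st.sampled_from([1, 2, 5, 10]),
        flip=st.booleans(),
    )
    def test_matches_negative_binomial_identity(self, x, y, n1, ratio, flip):
        # given x, the count y is NB with x+1 successes and p = N1/(N1+N2)
        n2 = n1 * ratio if not flip else max(n1 // ratio, 1)
        expected = nbinom.logpmf(y, x + 1, n1 / (n1 + n2))
        assert ac_log_pmf(y, x, n1, n2) == pytest.approx(expected, rel=1e-10)

    @pytest.mark.parametrize("ratio", [0.1, 0.5, 1.0, 2.0, 10.0])
    @pytest.mark.parametrize("x", [0, 3, 25, 100])
    def test_normalization(self, x, ratio):
        n1 = 10**6
        n2 = int(round(n1 * ratio))
        mean = (x + 1) * ratio
        sd = math.sqrt((x + 1) * ratio * (1 + ratio))
        upper = int(mean + 40 * sd + 200)
        total = np.exp(ac_log_pmf(np.arange(upper + 1), x, n1, n2)).sum()
        assert total == pytest.approx(1.0, abs=1e-10)


class TestTwoSidedP:
    def test_double_zero_is_twice_the_single_term(self):
        p = ac_two_sided_p(GenePairObs("g", 0, 0, 10**6, 10**6))
        assert p == pytest.approx(
            min(1.0, 2 * math.exp(ac_log_pmf(0, 0, 10**6, 10**6)))
        )

    @given(
        x=st.integers(0, 100),
        y=st.integers(0, 100),
        n1=st.sampled_from([10**4, 10**6]),
        ratio=st.sampled_from([1, 2, 5, 10]),
        k=st.integers(2, 7),
    )
    def test_depends_only_on_library_size_ratio(self, x, y, n1, ratio, k):
        n2 = n1 * ratio
        p1 = ac_two_sided_p(GenePairObs("g", x, y, n1, n2))
        p2 = ac_two_sided_p(GenePairObs("g", x, y, k * n1, k * n2))
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_brute_force_summation_oracle(self):
        x, y, n1, n2 = 5, 20, 10**6, 10**6
        ys = np.arange(0, 10 * (x + y))
        pmf = np.exp(ac_log_pmf(ys, x, n1, n2))
        lower = pmf[: y + 1].sum()
        upper = pmf[y:].sum()
        expected = min(1.0, 2 * min(lower, upper))
        got = ac_two_sided_p(GenePairObs("g", x, y, n1, n2))
        assert got == pytest.approx(expected, rel=1e-10)

    @given(
        x=st.integers(0, 50),
        y=st.integers(0, 50),
        scale=st.sampled_from([(10, 10), (10, 100), (100, 10), (2, 1)]),
    )
    def test_against_rational_oracle(self, x, y, scale):
        n1, n2 = scale[0] * 1000, scale[1] * 1000
        expected = float(two_sided_exact(x, y, n1, n2))
        got = ac_two_sided_p(GenePairObs("g", x, y, n1, n2))
        assert 0.0 < got <= 1.0
        assert got == pytest.approx(expected, rel=1e-10)


class TestLog2Ratio:
    @pytest.mark.parametrize(
        "x, y, n1, n2, expected",
        [
            (10, 10, 10**6, 10**6, 0.0),
            (10, 40, 10**6, 10**6, 2.0),
            (0, 8, 10**6, 10**6, 3.0),  # zero-substitution: log2(8/1)
            (10, 10, 10**6, 2 * 10**6, -1.0),
        ],
    )
    def test_values(self, x, y, n1, n2, expected):
        assert log2_ratio(GenePairObs("g", x, y, n1, n2)) == pytest.approx(expected)

    def test_double_zero_is_undefined(self):
        with pytest.raises(ChillseqError):
            log2_ratio(GenePairObs("g", 0, 0, 10, 10))


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03]) == [0.03]

    def test_hand_evaluated_step_up(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_all_equal_p_collapse(self):
        assert bh_fdr([0.2, 0.2, 0.2]) == pytest.approx([0.2] * 3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ChillseqError):
            bh_fdr([0.5, 1.2])

    @given(
        ps=st.lists(
            st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=200
        )
    )
    def test_matches_naive_double_loop(self, ps):
        def naive(p):
            n = len(p)
            order = sorted(range(n), key=lambda i: p[i])
            q = [0.0] * n
            for pos, i in enumerate(order):
                q[i] = min(
                    min(1.0, p[order[pos2]] * n / (pos2 + 1))
                    for pos2 in range(pos, n)
                )
            return q

        got = bh_fdr(ps)
        expected = naive(ps)
        assert got == pytest.approx(expected, abs=1e-12)


def _poisson_matrix(rng, n_null, planted, fold, mean, depth):
    n = n_null + planted
    lam_a = np.full(n, float(mean))
    lam_b = lam_a.copy()
    lam_b[:planted] *= fold
    counts = np.column_stack([rng.poisson(lam_a), rng.poisson(lam_b)])
    return CountMatrix(
        [f"g{i}" for i in range(n)], ["A", "B"], counts, [depth, depth]
    )


class TestRunContrast:
    def test_identical_columns_yield_zero_degs(self):
        counts = np.array([[5, 5], [100, 100], [0, 0]])
        m = CountMatrix(["g1", "g2", "g3"], ["A", "B"], counts, [10**6, 10**6])
        table = run_contrast(m, "A", "B")
        assert table.deg_ids() == set()
        # double-zero gene excluded from testing
        assert {r.gene_id for r in table.results} == {"g1", "g2"}

    def test_planted_eightfold_genes_all_called(self, rng):
        m = _poisson_matrix(rng, 980, 20, 8.0, 100, 10**6)
        table = run_contrast(m, "A", "B")
        planted = {f"g{i}" for i in range(20)}
        assert planted <= table.deg_ids()
        for g in planted:
            r = table[g]
            assert r.fdr <= 0.001 and abs(r.log2_ratio) >= 1.0
            # per-gene oracle agreement
            assert r.p == pytest.approx(
                ac_two_sided_p(GenePairObs(g, r.x, r.y, 10**6, 10**6)), rel=1e-12
            )

    def test_thresholds_are_a_conjunction(self):
        res = GeneDEResult("g", 10, 17, 0.8, 1e-6, 5e-4, "up", False)
        # fdr passes, ratio fails: built directly to pin the contract
        assert not (res.fdr <= 0.001 and abs(res.log2_ratio) >= 1.0)
        counts = np.array([[4000, 6000]])  # 1.5-fold at high depth
        m = CountMatrix(["g1"], ["A", "B"], counts, [10**7, 10**7])
        table = run_contrast(m, "A", "B")
        r = table["g1"]
        assert r.fdr <= 0.001 and abs(r.log2_ratio) < 1.0
        assert not r.is_deg

    def test_deg_calls_monotone_in_thresholds(self, rng):
        m = _poisson_matrix(rng, 300, 10, 4.0, 80, 10**6)
        loose = run_contrast(m, "A", "B", DEGThresholds(0.01, 0.5))
        tight_fdr = run_contrast(m, "A", "B", DEGThresholds(0.0001, 0.5))
        tight_ratio = run_contrast(m, "A", "B", DEGThresholds(0.01, 1.5))
        assert tight_fdr.deg_ids() <= loose.deg_ids()
        assert tight_ratio.deg_ids() <= loose.deg_ids()

    def test_unknown_sample_errors(self, small_matrix):
        with pytest.raises(KeyError):
            run_contrast(small_matrix, "A", "nope")


def _table(name, degs):
    # degs: list of (gene, direction)
    results = [
        GeneDEResult(g, 10, 40, 2.0 if d == "up" else -2.0, 1e-9, 1e-8, d, True)
        for g, d in degs
    ]
    return ContrastTable(name, "A", "B", 10**6, 10**6, results)


class TestSetOperations:
    def test_shared_degs_disjoint_and_identical(self):
        a = _table("c_vs_f", [("g1", "up"), ("g2", "down")])
        b = _table("c_vs_s", [("g3", "up")])
        assert shared_degs(a, b) == set()
        assert shared_degs(a, a) == {"g1", "g2"}

    def test_opposite_direction_flags_only_flips(self):
        a = _table("c_vs_f", [("g1", "down"), ("g2", "up"), ("g3", "up")])
        b = _table("c_vs_s", [("g1", "up"), ("g2", "down"), ("g3", "up")])
        assert opposite_direction(a, b) == [
            ("g1", "down", "up"),
            ("g2", "up", "down"),
        ]

    def test_venn_counts_match_direct_set_algebra(self):
        a = _table("cf", [("g1", "up"), ("g2", "down"), ("g3", "up")])
        b = _table("cs", [("g2", "down"), ("g3", "down"), ("g4", "up")])
        c = _table("fs", [("g4", "down")])
        venn = venn_counts([a, b, c])
        assert venn.per_contrast["cf"] == (3, 2, 1)
        assert venn.per_contrast["cs"] == (3, 1, 2)
        assert venn.per_contrast["fs"] == (1, 0, 1)
        assert venn.pairwise[("cf", "cs")] == 2
        assert venn.pairwise[("cs", "fs")] == 1
        assert venn.pairwise[("cf", "fs")] == 0

    def test_empty_tables_give_zero_counts(self):
        venn = venn_counts([_table("x", []), _table("y", []), _table("z", [])])
        assert all(v == (0, 0, 0) for v in venn.per_contrast.values())
        assert all(v == 0 for v in venn.pairwise.values())
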