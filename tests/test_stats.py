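"""Unit and property tests for the statistical primitives.

Exact tests are compared against brute-force enumeration oracles built on
scipy's distribution functions (independent of the gammaln-based
implementation), and against scipy/statsmodels reference routines.
"""

import itertools

import numpy as np
import pytest
import scipy.stats as ss
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from oceancog import (
    DegenerateDataError,
    ValidationError,
    bh_fdr,
    binomial_exact_counts,
    fisher_exact_2x2,
    fisher_exact_many,
    ranksum_exact,
    ranksum_exact_rows,
    welch_t,
    welch_t_rows,
)

RTOL = 1e-7


def fisher_oracle(a, b, c, d):
    """Two-sided point-probability Fisher p via scipy's hypergeometric pmf."""
    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, c1 - (c + d)), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = ss.hypergeom.pmf(support, n, r1, c1)
    p_obs = ss.hypergeom.pmf(a, n, r1, c1)
    return min(1.0, float(pmf[pmf <= p_obs * (1 + RTOL)].sum()))


def binomial_oracle(x1, x2, n1, n2):
    t = x1 + x2
    if t == 0:
        return 1.0
    p0 = n1 / (n1 + n2)
    k = np.arange(t + 1)
    pmf = ss.binom.pmf(k, t, p0)
    return min(1.0, float(pmf[pmf <= pmf[x1] * (1 + RTOL)].sum()))


def ranksum_oracle(x, y):
    """Exact distance-from-mean rank-sum p by pure-Python enumeration."""
    pooled = list(x) + list(y)
    ranks = ss.rankdata(pooled)
    w = ranks[: len(x)].sum()
    mu = len(x) * ranks.mean()
    n_extreme = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), len(x)):
        ws = sum(ranks[i] for i in combo)
        total += 1
        if abs(ws - mu) >= abs(w - mu) - 1e-9 * max(1.0, abs(mu)):
            n_extreme += 1
    return n_extreme / total


class TestFisherExact:
    def test_identical_columns_give_p_one(self):
        assert fisher_exact_2x2(5, 95, 5, 95).p_value == 1.0

    def test_diagonal_table_enumeration(self):
        # Hypergeom(N=6, K=3, n=3): P(0) + P(3) = 2/20
        res = fisher_exact_2x2(3, 0, 0, 3)
        assert res.p_value == pytest.approx(0.1, rel=1e-12)

    def test_matches_scipy_two_sided(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            a, b, c, d = rng.integers(0, 40, size=4)
            if a + b + c + d == 0:
                continue
            expect = ss.fisher_exact([[a, b], [c, d]])[1]
            got = fisher_exact_2x2(int(a), int(b), int(c), int(d)).p_value
            assert got == pytest.approx(expect, rel=1e-6)

    def test_rejects_negative_entries(self):
        with pytest.raises(ValidationError):
            fisher_exact_2x2(-1, 2, 3, 4)

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(5)
        n1, n2 = 500, 700
        x1 = rng.integers(0, 60, size=200)
        x2 = rng.integers(0, 60, size=200)
        p_vec = fisher_exact_many(x1, x2, n1, n2)
        for i in range(len(x1)):
            scalar = fisher_exact_2x2(
                int(x1[i]), n1 - int(x1[i]), int(x2[i]), n2 - int(x2[i])
            ).p_value
            assert p_vec[i] == pytest.approx(scalar, rel=1e-9)

    @given(
        st.integers(0, 60), st.integers(0, 60), st.integers(0, 60), st.integers(0, 60)
    )
    @settings(max_examples=150, deadline=None)
    def test_matches_bruteforce_oracle(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        assert fisher_exact_2x2(a, b, c, d).p_value == pytest.approx(
            fisher_oracle(a, b, c, d), rel=1e-6
        )


class TestBinomialExact:
    def test_extreme_split_closed_form(self):
        # Binomial(10, 1/2): both point masses at the extremes
        res = binomial_exact_counts(0, 10, 1000, 1000)
        assert res.p_value == pytest.approx(2 * 0.5**10, rel=1e-12)

    def test_symmetric_mode_p_one(self):
        assert binomial_exact_counts(5, 5, 1000, 1000).p_value == 1.0

    def test_zero_total_uninformative(self):
        res = binomial_exact_counts(0, 0, 10, 10)
        assert res.p_value == 1.0
        assert "uninformative" in res.method

    @given(st.integers(0, 30), st.integers(0, 30), st.integers(1, 500), st.integers(1, 500))
    @settings(max_examples=150, deadline=None)
    def test_matches_bruteforce_oracle(self, x1, x2, n1, n2):
        if x1 > n1 or x2 > n2:
            return
        got = binomial_exact_counts(x1, x2, n1, n2).p_value
        assert got == pytest.approx(binomial_oracle(x1, x2, n1, n2), rel=1e-6)


class TestWelch:
    def test_identical_samples(self):
        res = welch_t([1, 2, 3], [1, 2, 3])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_hand_evaluated_example(self):
        res = welch_t([1, 2, 3, 4], [3, 4, 5, 6])
        assert res.statistic == pytest.approx(-2.1909, abs=1e-4)
        assert res.df == pytest.approx(6.0, abs=1e-9)
        assert res.p_value == pytest.approx(0.0708, abs=2e-3)

    def test_antisymmetry(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=6), rng.normal(1, 2, size=9)
        fwd, rev = welch_t(x, y), welch_t(y, x)
        assert fwd.statistic == pytest.approx(-rev.statistic)
        assert fwd.p_value == pytest.approx(rev.p_value)

    def test_matches_scipy(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            x = rng.normal(size=rng.integers(2, 12))
            y = rng.normal(0.5, 2.0, size=rng.integers(2, 12))
            res = welch_t(x, y)
            ref = ss.ttest_ind(x, y, equal_var=False)
            assert res.statistic == pytest.approx(ref.statistic, rel=1e-9)
            assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_both_constant_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            welch_t([2, 2, 2], [5, 5, 5])

    def test_rowwise_matches_scalar(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(40, 5))
        Y = rng.normal(0.3, 1.5, size=(40, 8))
        t, df, p = welch_t_rows(X, Y)
        for i in range(0, 40, 7):
            res = welch_t(X[i], Y[i])
            assert t[i] == pytest.approx(res.statistic, rel=1e-12)
            assert df[i] == pytest.approx(res.df, rel=1e-12)
            assert p[i] == pytest.approx(res.p_value, rel=1e-12)

    def test_rowwise_constant_rows(self):
        X = np.full((2, 4), 3.0)
        Y = np.vstack([np.full(5, 3.0), np.full(5, 9.0)])
        _, _, p = welch_t_rows(X, Y)
        assert p[0] == 1.0
        assert p[1] < 1e-100


class TestRanksum:
    def test_separated_small_samples(self):
        # all C(4,2)=6 assignments; W in {3,4,5,5,6,7}, observed 3
        res = ranksum_exact([1, 2], [3, 4])
        assert res.p_value == pytest.approx(2 / 6, rel=1e-12)

    def test_fully_tied_exchangeable(self):
        assert ranksum_exact([1, 2], [1, 2]).p_value == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            ranksum_exact([], [1.0])

    @given(
        st.lists(st.integers(0, 6), min_size=1, max_size=4),
        st.lists(st.integers(0, 6), min_size=1, max_size=5),
    )
    @settings(max_examples=120, deadline=None)
    def test_matches_enumeration_oracle_with_ties(self, x, y):
        got = ranksum_exact(x, y).p_value
        assert got == pytest.approx(ranksum_oracle(x, y), rel=1e-9)

    def test_tie_free_matches_scipy_exact(self):
        rng = np.random.default_rng(21)
        for _ in range(25):
            pooled = rng.permutation(rng.normal(size=9))
            x, y = pooled[:4], pooled[4:]
            got = ranksum_exact(x, y).p_value
            ref = ss.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert got == pytest.approx(ref.pvalue, rel=1e-9)

    def test_rowwise_matches_scalar(self):
        rng = np.random.default_rng(31)
        values = rng.normal(size=(30, 10))
        values[::4] = np.round(values[::4])  # inject ties
        low = [1, 4, 7]
        w, p = ranksum_exact_rows(values, low)
        high_idx = [i for i in range(10) if i not in low]
        for i in range(0, 30, 5):
            res = ranksum_exact(values[i, low], values[i, high_idx])
            assert w[i] == pytest.approx(res.statistic)
            assert p[i] == pytest.approx(res.p_value, rel=1e-9)


class TestBH:
    def test_stepup_by_hand(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.37]).tolist() == [0.37]

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=500)
        expect = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(bh_fdr(p), expect)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    @settings(max_examples=100, deadline=None)
    def test_dominates_and_monotone(self, p):
        q = bh_fdr(p)
        assert np.all(q >= np.asarray(p) - 1e-12)
        assert np.all(q <= 1.0)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_bounded_by_bonferroni(self):
        rng = np.random.default_rng(17)
        p = rng.uniform(size=200) ** 3
        q = bh_fdr(p)
        assert np.all(q <= np.minimum(1.0, p * len(p)) + 1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.5])


def test_fisher_null_rejection_rate_is_conservative():
    """Under equal proportions, the exact test rejects at most at nominal α."""
    rng = np.random.default_rng(42)
    n1 = n2 = 2000
    x1 = rng.binomial(n1, 0.01, size=10_000)
    x2 = rng.binomial(n2, 0.01, size=10_000)
    p = fisher_exact_many(x1, x2, n1, n2)
    for alpha in (0.01, 0.05):
        rate = float((p <= alpha).mean())
        # allow Monte-Carlo slack: 3 binomial SDs above alpha
        assert rate <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / 10_000)
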