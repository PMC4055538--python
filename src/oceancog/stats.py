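"""Statistical primitives for count-based functional profiling.

Everything the screening stages need lives here, implemented directly so the
decision rules are explicit and testable against brute-force enumeration:

* :func:`fisher_exact_2x2` — conditional hypergeometric exact test with the
  two-sided point-probability (minimum-likelihood) rule;
* :func:`binomial_exact_counts` — the dispersion-free conditional binomial
  analogue for a pair of libraries of known size;
* :func:`welch_t` — unequal-variance t-test with Welch–Satterthwaite df;
* :func:`ranksum_exact` — Wilcoxon rank-sum with midranks and an exact
  two-sided p by enumeration of all group assignments;
* :func:`bh_fdr` — Benjamini–Hochberg step-up adjusted p-values.

Discrete two-sided p-values follow the point-probability rule: the p-value is
the total null probability of all outcomes whose point probability does not
exceed that of the observed outcome, with a relative tolerance of 1e-7 when
comparing probabilities so that symmetric ties are always included.

The exact rank-sum p uses the distance-from-null-mean rule over the
enumerated permutation distribution (the probability of a rank sum at least
as far from its null expectation as the observed one). For tie-free data
this coincides with the classical two-tailed rule.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from math import comb, log1p

import numpy as np
from scipy.special import gammaln
from scipy.stats import rankdata
from scipy.stats import t as t_dist

from .errors import DegenerateDataError, ValidationError

__all__ = [
    "TestResult",
    "fisher_exact_2x2",
    "fisher_exact_many",
    "binomial_exact_counts",
    "welch_t",
    "welch_t_rows",
    "ranksum_exact",
    "ranksum_exact_rows",
    "bh_fdr",
    "EXACT_ENUMERATION_LIMIT",
]

#: relative slack when comparing point probabilities of discrete outcomes
_POINT_PROB_RTOL = 1e-7
_LOG_RTOL = log1p(_POINT_PROB_RTOL)

#: largest number of group assignments enumerated by the exact rank-sum test
EXACT_ENUMERATION_LIMIT = 1_000_000

_TINY = np.finfo(float).tiny


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test (p is two-sided, in (0, 1])."""

    statistic: float
    p_value: float
    method: str
    df: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValidationError(f"p_value {self.p_value} outside (0, 1]")


def _log_choose(n, k):
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def _check_counts(*values: int) -> None:
    for v in values:
        if v != int(v) or v < 0:
            raise ValidationError(f"counts must be non-negative integers, got {v!r}")


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    Returns the two-sided p-value under the conditional hypergeometric null
    (all margins fixed), summing the probabilities of every table whose
    point probability is at most that of the observed table. The statistic
    is the sample odds ratio ``(a d)/(b c)``.
    """
    _check_counts(a, b, c, d)
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0:
        raise ValidationError("at least one table margin must be positive")
    lo, hi = max(0, c1 - r2), min(r1, c1)
    support = np.arange(lo, hi + 1)
    logpmf = (
        _log_choose(r1, support) + _log_choose(r2, c1 - support) - _log_choose(n, c1)
    )
    obs = logpmf[a - lo]
    p = float(np.exp(logpmf[logpmf <= obs + _LOG_RTOL]).sum())
    p = min(1.0, max(p, _TINY))
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = np.divide(a * d, b * c) if b * c else (np.inf if a * d else np.nan)
    return TestResult(float(odds), p, "fisher-exact")


def fisher_exact_many(
    x1: np.ndarray, x2: np.ndarray, n1: int, n2: int
) -> np.ndarray:
    """Vectorized two-sided Fisher p-values for many (x1, rest1, x2, rest2) tables.

    ``x1`` and ``x2`` are per-feature counts out of fixed library sizes
    ``n1`` and ``n2``; each feature forms the table
    ``[[x1, n1 - x1], [x2, n2 - x2]]``. Same decision rule as
    :func:`fisher_exact_2x2`.
    """
    x1 = np.asarray(x1, dtype=np.int64)
    x2 = np.asarray(x2, dtype=np.int64)
    if x1.shape != x2.shape:
        raise ValidationError("x1 and x2 must have equal shapes")
    if np.any(x1 < 0) or np.any(x2 < 0) or np.any(x1 > n1) or np.any(x2 > n2):
        raise ValidationError("counts must satisfy 0 <= x <= library size")
    total = x1 + x2
    kmax = int(total.max(initial=0))
    k = np.arange(kmax + 1)
    # support for feature i: max(0, K - n2) <= k <= min(K, n1)
    K = total[:, None]
    valid = (k >= np.maximum(0, K - n2)) & (k <= np.minimum(K, n1))
    with np.errstate(invalid="ignore"):
        logpmf = (
            _log_choose(n1, k)[None, :]
            + _log_choose(n2, np.maximum(K - k, 0))
            - _log_choose(n1 + n2, K)
        )
    logpmf = np.where(valid, logpmf, -np.inf)
    obs = np.take_along_axis(logpmf, x1[:, None], axis=1)
    include = logpmf <= obs + _LOG_RTOL
    p = np.exp(np.where(include & valid, logpmf, -np.inf)).sum(axis=1)
    return np.clip(p, _TINY, 1.0)


def binomial_exact_counts(x1: int, x2: int, n1: int, n2: int) -> TestResult:
    """Exact test for equal relative abundance in two libraries.

    Conditional on the total ``t = x1 + x2``, ``x1`` is Binomial(t, n1/(n1+n2))
    under the null; the two-sided p follows the point-probability rule. A
    total of zero carries no information and yields p = 1 (flagged in the
    method string).
    """
    _check_counts(x1, x2)
    if n1 <= 0 or n2 <= 0:
        raise ValidationError("library sizes must be positive")
    if x1 > n1 or x2 > n2:
        raise ValidationError("counts cannot exceed library sizes")
    t = x1 + x2
    stat = x1 / n1 - x2 / n2
    if t == 0:
        return TestResult(stat, 1.0, "binomial-exact (zero total, uninformative)")
    p0 = n1 / (n1 + n2)
    k = np.arange(t + 1)
    logpmf = _log_choose(t, k) + k * np.log(p0) + (t - k) * np.log1p(-p0)
    obs = logpmf[x1]
    p = float(np.exp(logpmf[logpmf <= obs + _LOG_RTOL]).sum())
    return TestResult(stat, min(1.0, max(p, _TINY)), "binomial-exact")


def welch_t(x, y) -> TestResult:
    """Welch's unequal-variance t-test (two-sided).

    ``t = (mean x - mean y) / sqrt(sx²/nx + sy²/ny)`` with the
    Welch–Satterthwaite degrees of freedom. Requires two observations per
    sample and at least one sample with positive variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or len(x) < 2 or len(y) < 2:
        raise ValidationError("welch_t needs two 1-d samples of size >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        raise DegenerateDataError("both samples are constant; t is undefined")
    ax, ay = vx / len(x), vy / len(y)
    se = np.sqrt(ax + ay)
    t = (x.mean() - y.mean()) / se
    df = (ax + ay) ** 2 / (
        (ax**2 / (len(x) - 1)) + (ay**2 / (len(y) - 1))
    )
    p = 2.0 * float(t_dist.sf(abs(t), df))
    return TestResult(float(t), min(1.0, max(p, _TINY)), "welch-t", df=float(df))


def welch_t_rows(X: np.ndarray, Y: np.ndarray):
    """Row-wise Welch's test between two column groups.

    ``X`` (m × nx) and ``Y`` (m × ny) hold the two groups' values for m
    features. Rows where both groups are constant get t = 0, p = 1 when the
    means agree, and p = tiny when they differ (a deterministic separation).
    Returns ``(t, df, p)`` arrays.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    nx, ny = X.shape[1], Y.shape[1]
    if nx < 2 or ny < 2:
        raise ValidationError("each group needs >= 2 columns")
    mx, my = X.mean(axis=1), Y.mean(axis=1)
    ax = X.var(axis=1, ddof=1) / nx
    ay = Y.var(axis=1, ddof=1) / ny
    se = np.sqrt(ax + ay)
    diff = mx - my
    degenerate = se == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(degenerate, 0.0, diff / np.where(degenerate, 1.0, se))
        df = (ax + ay) ** 2 / (
            ax**2 / (nx - 1) + ay**2 / (ny - 1)
        )
    df = np.where(degenerate, float(nx + ny - 2), df)
    p = 2.0 * t_dist.sf(np.abs(t), df)
    p = np.where(degenerate & (diff != 0.0), _TINY, p)
    p = np.where(degenerate & (diff == 0.0), 1.0, p)
    return t, df, np.clip(p, _TINY, 1.0)


@lru_cache(maxsize=32)
def _assignment_indices(n: int, k: int) -> np.ndarray:
    """All C(n, k) index subsets as an array of shape (C, k)."""
    if comb(n, k) > EXACT_ENUMERATION_LIMIT:
        raise ValidationError(
            f"C({n},{k}) exceeds the exact enumeration limit "
            f"{EXACT_ENUMERATION_LIMIT}"
        )
    return np.array(list(itertools.combinations(range(n), k)), dtype=np.intp)


def _ranksum_p_from_ranks(ranks: np.ndarray, k: int, w_obs: float) -> float:
    """Exact distance-from-mean p for a rank sum over all C(n, k) subsets."""
    combos = _assignment_indices(len(ranks), k)
    w_all = ranks[combos].sum(axis=1)
    mu = k * ranks.mean()
    tol = 1e-9 * max(1.0, abs(mu))
    extreme = np.abs(w_all - mu) >= abs(w_obs - mu) - tol
    return float(extreme.mean())


def ranksum_exact(x, y) -> TestResult:
    """Wilcoxon rank-sum test with midranks and exact enumeration.

    The statistic is the sum of the pooled midranks of ``x``. The two-sided
    p-value is the exact permutation probability of a rank sum at least as
    far from its null expectation as observed, enumerating all
    ``C(nx+ny, nx)`` group assignments. Beyond
    :data:`EXACT_ENUMERATION_LIMIT` assignments a normal approximation with
    tie correction is used (noted in the method string).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("rank-sum test requires non-empty samples")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    w = float(ranks[: len(x)].sum())
    n, k = len(pooled), len(x)
    if comb(n, k) <= EXACT_ENUMERATION_LIMIT:
        p = _ranksum_p_from_ranks(ranks, k, w)
        return TestResult(w, min(1.0, max(p, _TINY)), "ranksum-exact")
    # normal approximation with tie correction on the rank variance
    mu = k * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / ((n - 1) * n * (n + 1))
    sigma2 = k * (n - k) * (n + 1) / 12.0 * (1.0 - tie_term)
    if sigma2 <= 0.0:
        return TestResult(w, 1.0, "ranksum-normal (all values tied)")
    from scipy.stats import norm

    z = (w - mu) / np.sqrt(sigma2)
    p = 2.0 * float(norm.sf(abs(z)))
    return TestResult(w, min(1.0, max(p, _TINY)), "ranksum-normal-approx")


def ranksum_exact_rows(values: np.ndarray, group_idx, chunk: int = 256):
    """Row-wise exact rank-sum p-values for a fixed group of columns.

    ``values`` is (m × n); ``group_idx`` the column indices of the first
    group (size k). Enumerates all C(n, k) assignments once and reuses them
    across rows. Returns ``(w, p)`` arrays.
    """
    values = np.asarray(values, dtype=float)
    group_idx = np.asarray(group_idx, dtype=np.intp)
    m, n = values.shape
    k = len(group_idx)
    if k == 0 or k >= n:
        raise ValidationError("group must be a non-empty proper subset of columns")
    combos = _assignment_indices(n, k)
    ranks = rankdata(values, axis=1)
    w = ranks[:, group_idx].sum(axis=1)
    mu = k * ranks.mean(axis=1)
    p = np.empty(m)
    for start in range(0, m, chunk):
        stop = min(start + chunk, m)
        block = ranks[start:stop]
        w_all = block[:, combos].sum(axis=2)  # (rows, C)
        mu_b = mu[start:stop, None]
        tol = 1e-9 * np.maximum(1.0, np.abs(mu_b))
        extreme = np.abs(w_all - mu_b) >= np.abs(w[start:stop, None] - mu_b) - tol
        p[start:stop] = extreme.mean(axis=1)
    return w, np.clip(p, _TINY, 1.0)


def bh_fdr(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    ``q(i) = min_{j >= i} p(j) * m / j`` over the sorted p-values, capped
    at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValidationError("bh_fdr expects a 1-d array")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
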