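"""Two-sample tests: Welch unequal-variance t and Wilcoxon-Mann-Whitney.

Both tests are implemented from their defining formulas (only the reference
distributions come from :mod:`scipy.stats`). The WMW test uses the normal
approximation with continuity correction 0.5 and the midrank tie
correction; an exact-enumeration mode over all group assignments is
available for small pooled sizes and serves as the testing oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

__all__ = ["TestResult", "welch_t", "wmw_test", "wmw_exact_p", "compare_p"]


@dataclass(frozen=True)
class TestResult:
    """Outcome of one two-sample test on one pair of samples."""

    statistic: float
    p_value: float
    test_name: str
    df: float | None = None
    degenerate: bool = False


def welch_t(x, y) -> TestResult:
    """Welch two-sample t-test (unequal variances, two-sided).

    statistic = (mean(x) - mean(y)) / sqrt(s1^2/n1 + s2^2/n2) with unbiased
    sample variances; degrees of freedom by Welch-Satterthwaite, kept
    fractional; p from Student's t.

    Degenerate samples (both variances zero) yield p = 1 when the means are
    equal and p = 0 otherwise, flagged via ``degenerate``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("welch_t requires at least 2 observations per group")
    m1, m2 = x.mean(), y.mean()
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    if v1 == 0.0 and v2 == 0.0:
        equal = m1 == m2
        return TestResult(
            statistic=0.0 if equal else math.copysign(math.inf, m1 - m2),
            p_value=1.0 if equal else 0.0,
            test_name="welch_t",
            df=float(min(n1, n2) - 1),
            degenerate=True,
        )
    se2 = v1 / n1 + v2 / n2
    t = (m1 - m2) / math.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TestResult(statistic=float(t), p_value=float(p), test_name="welch_t", df=float(df))


def _u_less(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Mann-Whitney U (pairs with x < y, ties counted half) and the tie term.

    Computed from midranks of the pooled sample: the rank sum of x gives the
    number of pairs with x > y plus half the ties; U is its complement. The
    tie term is ``sum(t^3 - t)`` over tie groups, used in the variance.
    """
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled, method="average")
    r1 = ranks[:n1].sum()
    u_greater = r1 - n1 * (n1 + 1) / 2.0
    u = n1 * n2 - u_greater
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float((counts.astype(float) ** 3 - counts).sum())
    return float(u), tie_term


def wmw_test(x, y) -> TestResult:
    """Wilcoxon-Mann-Whitney rank-sum test, two-sided.

    U counts pairs ``(x_i, y_j)`` with ``x_i < y_j`` plus half the tied
    pairs. The standardized statistic applies a continuity correction of 0.5
    and the midrank tie correction to the variance; p comes from the normal
    approximation. If every pooled value is tied the result is degenerate
    with p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 1 or n2 < 1:
        raise ValueError("wmw_test requires at least 1 observation per group")
    u, tie_term = _u_less(x, y)
    n = n1 + n2
    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * (n + 1 - tie_term / (n * (n - 1)))
    if var <= 0.0:
        return TestResult(statistic=0.0, p_value=1.0, test_name="wmw", degenerate=True)
    d = u - mu
    z = math.copysign(max(abs(d) - 0.5, 0.0), d) / math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return TestResult(statistic=float(z), p_value=float(min(p, 1.0)), test_name="wmw")


def wmw_exact_p(x, y) -> float:
    """Exact two-sided WMW p-value by enumerating all group assignments.

    Enumerates every ``C(n1+n2, n1)`` split of the pooled values, computes U
    for each, and returns ``min(1, 2 * min(P(U <= u), P(U >= u)))``. Feasible
    for pooled sizes up to ~16; intended as an oracle for the normal
    approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1 = x.size
    pooled = np.concatenate([x, y])
    n = pooled.size
    if n > 20:
        raise ValueError("exact enumeration is limited to pooled sizes <= 20")
    u_obs, _ = _u_less(x, y)
    # the permutation distribution depends on the pooled values only through
    # their midranks, so rank once and enumerate rank subsets
    ranks = stats.rankdata(pooled, method="average")
    n2 = n - n1
    subsets = np.array(list(combinations(range(n), n1)))
    r1 = ranks[subsets].sum(axis=1)
    us = n1 * n2 - (r1 - n1 * (n1 + 1) / 2.0)
    eps = 1e-9
    p_lo = np.mean(us <= u_obs + eps)
    p_hi = np.mean(us >= u_obs - eps)
    return float(min(1.0, 2.0 * min(p_lo, p_hi)))


def compare_p(p_wmw: float, p_t: float) -> bool:
    """True iff the WMW p-value is strictly smaller than the t-test p-value."""
    if not (0.0 <= p_wmw <= 1.0 and 0.0 <= p_t <= 1.0):
        raise ValueError("p-values must lie in [0, 1]")
    return p_wmw < p_t
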