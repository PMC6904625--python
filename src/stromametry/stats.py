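"""Two-sample and one-sample tests with exact small-sample modes.

The size comparisons in this pipeline involve tiny groups (tens of
vesicles), where asymptotic p-values are unreliable, so the rank tests
carry exact modes built from first principles:

* :func:`mann_whitney` enumerates every assignment of the pooled ranks to
  the two groups when the pooled size is within the enumeration bound and
  there are no ties, giving the exact permutation null of the U statistic.
* :func:`ratio_below_one` is a one-sample Wilcoxon signed-rank test of the
  width:length ratios against 1, exact for small n via the signed-rank
  distribution computed by dynamic programming.

Two-sided p-values are twice the smaller tail probability, capped at 1.
:func:`welch_t` wraps the standard unequal-variance t-test with a p = 1
convention for degenerate (zero-variance, equal-mean) inputs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = ["TestResult", "mann_whitney", "welch_t", "ratio_below_one"]

#: Largest pooled sample size for which the Mann-Whitney exact mode
#: enumerates all C(n, n1) group labelings.
EXACT_ENUMERATION_BOUND = 12

#: Largest n for which the signed-rank test uses the exact distribution.
WILCOXON_EXACT_BOUND = 20


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test.

    ``mode`` records whether the p-value came from an exact null
    distribution or a normal approximation.
    """

    method: str
    statistic: float
    p_value: float
    n: tuple[int, ...]
    alternative: str = "two-sided"
    mode: str = "exact"

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value must be in (0, 1], got {self.p_value}")


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for group x: number of (x_i, y_j) pairs with x_i > y_j (+0.5 per tie)."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact mode (full enumeration of all group labelings of the pooled
    sample) when ``len(x) + len(y) <= 12`` and there are no ties across or
    within groups; otherwise the normal approximation with tie and
    continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    u_obs = _u_statistic(x, y)

    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size

    if n1 + n2 <= EXACT_ENUMERATION_BOUND and not has_ties:
        # Enumerate every way of labeling n1 of the pooled values as group x.
        total = 0
        le = 0  # labelings with U <= observed
        ge = 0  # labelings with U >= observed
        idx = range(n1 + n2)
        for combo in itertools.combinations(idx, n1):
            sel = np.zeros(n1 + n2, dtype=bool)
            sel[list(combo)] = True
            u = _u_statistic(pooled[sel], pooled[~sel])
            total += 1
            if u <= u_obs + 1e-9:
                le += 1
            if u >= u_obs - 1e-9:
                ge += 1
        p = min(1.0, 2.0 * min(le, ge) / total)
        return TestResult("mann_whitney", u_obs, p, (n1, n2), mode="exact")

    # Normal approximation with tie correction and continuity correction.
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:
        return TestResult("mann_whitney", u_obs, 1.0, (n1, n2), mode="approximate")
    z = (abs(u_obs - mu) - 0.5) / math.sqrt(sigma2)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * float(sps.norm.sf(z)))
    p = max(p, np.finfo(float).tiny)
    return TestResult("mann_whitney", u_obs, p, (n1, n2), mode="approximate")


def welch_t(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Welch's unequal-variance t-test with Satterthwaite df, two-sided."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("welch_t requires at least 2 observations per group")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            return TestResult("welch_t", 0.0, 1.0, (x.size, y.size), mode="approximate")
        raise ValueError("zero variance in both groups with unequal means")
    t, p = sps.ttest_ind(x, y, equal_var=False)
    p = max(float(p), np.finfo(float).tiny)
    return TestResult("welch_t", float(t), p, (x.size, y.size), mode="approximate")


def _signed_rank_distribution(n: int) -> np.ndarray:
    """Null pmf of the Wilcoxon W+ statistic for n untied nonzero values.

    Dynamic programming over the generating polynomial
    prod_{r=1..n} (1 + t^r) / 2^n.
    """
    max_w = n * (n + 1) // 2
    counts = np.zeros(max_w + 1, dtype=float)
    counts[0] = 1.0
    for r in range(1, n + 1):
        counts[r:] += counts[: max_w + 1 - r].copy()
    return counts / counts.sum()


def ratio_below_one(ratios: Sequence[float]) -> TestResult:
    """Wilcoxon signed-rank test of width:length ratios against 1.

    Ratios exactly equal to 1 are dropped (standard zero handling); if all
    are 1 the result is p = 1 by convention. Exact null distribution for
    n <= 20 nonzero differences, normal approximation with continuity
    correction above that. Two-sided p with the direction implied by the
    statistic (W+ near 0 means ratios below 1).
    """
    r = np.asarray(ratios, dtype=float)
    if r.size < 5:
        raise ValueError("ratio_below_one requires at least 5 ratios")
    if np.any((r <= 0) | (r > 1)):
        raise ValueError("ratios must lie in (0, 1]")
    d = r - 1.0
    nz = d[d != 0]
    n = nz.size
    if n == 0:
        return TestResult("wilcoxon_vs_1", 0.0, 1.0, (r.size,), mode="exact")

    ranks = sps.rankdata(np.abs(nz))
    w_plus = float(ranks[nz > 0].sum())
    has_ties = np.unique(np.abs(nz)).size < n

    if n <= WILCOXON_EXACT_BOUND and not has_ties:
        pmf = _signed_rank_distribution(n)
        w = int(round(w_plus))
        p_le = float(pmf[: w + 1].sum())
        p_ge = float(pmf[w:].sum())
        p = min(1.0, 2.0 * min(p_le, p_ge))
        p = max(p, np.finfo(float).tiny)
        return TestResult("wilcoxon_vs_1", w_plus, p, (r.size,), mode="exact")

    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(nz), return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term / 48.0
    z = (abs(w_plus - mu) - 0.5) / math.sqrt(sigma2)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * float(sps.norm.sf(z)))
    p = max(p, np.finfo(float).tiny)
    return TestResult("wilcoxon_vs_1", w_plus, p, (r.size,), mode="approximate")
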