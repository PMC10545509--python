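"""Nonparametric group comparison of psychometric parameters.

Kruskal-Wallis omnibus tests with the eta-squared-H effect size
``(H - k + 1) / (n - k)``, Dunn's z-tests for post hoc pairwise comparisons
(tie-corrected, unadjusted p by default with an optional Holm correction),
Spearman correlations, and the upper-quantile outlier-flagging rule used for
sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

__all__ = [
    "KWResult",
    "DunnResult",
    "kruskal_wallis",
    "kw_pvalue",
    "eta_squared_h",
    "dunn_test",
    "dunn_all_pairs",
    "spearman",
    "flag_outliers",
]


@dataclass(frozen=True)
class KWResult:
    """Tie-corrected Kruskal-Wallis omnibus result with effect size."""

    H: float
    df: int
    p: float
    eta2_H: float


@dataclass(frozen=True)
class DunnResult:
    """One pairwise Dunn comparison: labels, standardized rank-mean gap, p."""

    pair: tuple
    z: float
    p: float


def eta_squared_h(H: float, k: int, n: int) -> float:
    """Effect size of a Kruskal-Wallis test: (H - k + 1) / (n - k).

    Expressed as a proportion; may be slightly negative when H falls below
    its null expectation k - 1 (reported as computed, not clipped).
    """
    if n <= k:
        raise ValueError(f"need more observations than groups, got n={n}, k={k}")
    return (H - k + 1) / (n - k)


def kw_pvalue(H: float, df: int) -> float:
    """Upper-tail chi-square p-value for a Kruskal-Wallis statistic.

    Lets a reported H with k - 1 degrees of freedom be converted back to its
    p-value without the raw data.
    """
    if H < 0 or df < 1:
        raise ValueError(f"need H >= 0 and df >= 1, got H={H}, df={df}")
    return float(stats.chi2.sf(H, df))


def kruskal_wallis(groups) -> KWResult:
    """Kruskal-Wallis H over k >= 2 groups, with tie correction and eta2_H.

    All values identical across groups is a valid degenerate case
    (H = 0, p = 1), not an error.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    k = len(groups)
    n = sum(g.size for g in groups)
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return KWResult(H=0.0, df=k - 1, p=1.0, eta2_H=eta_squared_h(0.0, k, n))
    H, p = stats.kruskal(*groups)
    return KWResult(H=float(H), df=k - 1, p=float(p),
                    eta2_H=eta_squared_h(float(H), k, n))


def dunn_test(groups, pair: tuple[int, int],
              labels=None) -> DunnResult:
    """Dunn's post hoc z-test for one pair of groups.

    Ranks are computed jointly over all k groups.  The statistic is

        z = (Rbar_i - Rbar_j) / sqrt([N(N+1)/12 - T/(12(N-1))] (1/n_i + 1/n_j))

    with tie term T = sum(t^3 - t) over tied value groups; positive z means
    group i tends to larger values than group j.  p is the two-sided normal
    tail.  All values tied gives an undefined z (error).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    i, j = pair
    pooled = np.concatenate(groups)
    N = pooled.size
    ranks = stats.rankdata(pooled)
    sizes = [g.size for g in groups]
    offsets = np.cumsum([0] + sizes)
    rank_means = [ranks[offsets[g]:offsets[g + 1]].mean() for g in range(len(groups))]
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var_unit = N * (N + 1) / 12.0 - tie_term / (12.0 * (N - 1))
    se2 = var_unit * (1.0 / sizes[i] + 1.0 / sizes[j])
    if se2 <= 0:
        raise ValueError("zero pooled rank variance: all values tied")
    z = (rank_means[i] - rank_means[j]) / np.sqrt(se2)
    p = 2.0 * stats.norm.sf(abs(z))
    name = (labels[i], labels[j]) if labels is not None else (i, j)
    return DunnResult(pair=name, z=float(z), p=float(p))


def dunn_all_pairs(groups, labels=None, holm: bool = False) -> list[DunnResult]:
    """Dunn tests for every group pair; optional Holm step-down adjustment."""
    results = [dunn_test(groups, (i, j), labels)
               for i, j in combinations(range(len(groups)), 2)]
    if holm:
        order = np.argsort([r.p for r in results])
        m = len(results)
        adjusted = [None] * m
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, min(1.0, (m - rank) * results[idx].p))
            adjusted[idx] = running
        results = [DunnResult(r.pair, r.z, adj)
                   for r, adj in zip(results, adjusted)]
    return results


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a t-approximation p-value (n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need paired samples with n >= 4")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def flag_outliers(values, q: float = 0.975) -> np.ndarray:
    """Flag values strictly above the q-th empirical quantile.

    Uses the linear-interpolation quantile convention.  Mirrors the
    sensitivity rule of excluding upper-bound threshold outliers
    (> 97.5th percentile) before re-running the group analyses.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    cutoff = np.quantile(values, q)
    return values > cutoff
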