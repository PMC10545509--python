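"""ROC analysis of the intelligibility threshold as a diagnostic classifier.

Given fitted 50% thresholds for a patient group (cases) and healthy controls,
quantifies how well the threshold separates them.  Higher threshold means
case.  Two AUC estimators are provided:

* empirical — Mann-Whitney U scaled to [0, 1] (ties count one half), with a
  DeLong 95% confidence interval;
* binormal — ``Phi((mu_case - mu_control) / sqrt(sd_case^2 + sd_control^2))``
  from sample moments, with a bootstrap confidence interval.

The empirical estimator is invariant under any strictly monotone transform
of the scores; the binormal one only under affine maps, and it can be biased
when group distributions are far from normal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["ROCResult", "empirical_auc", "binormal_auc", "roc_curve_points"]


@dataclass(frozen=True)
class ROCResult:
    """AUC with a 95% CI and the ROC curve in (FPR, TPR) coordinates."""

    auc: float
    ci_lo: float
    ci_hi: float
    method: str
    ci_method: str
    fpr: np.ndarray = field(repr=False)
    tpr: np.ndarray = field(repr=False)


def roc_curve_points(cases, controls) -> tuple[np.ndarray, np.ndarray]:
    """Empirical ROC curve: (FPR, TPR) from (0,0) to (1,1), both monotone."""
    cases = np.asarray(cases, dtype=float)
    controls = np.asarray(controls, dtype=float)
    thresholds = np.unique(np.concatenate([cases, controls]))[::-1]
    tpr = [0.0]
    fpr = [0.0]
    for t in thresholds:
        tpr.append(np.mean(cases >= t))
        fpr.append(np.mean(controls >= t))
    return np.asarray(fpr), np.asarray(tpr)


def _placements(cases: np.ndarray, controls: np.ndarray):
    """DeLong placement values: per-case and per-control win fractions."""
    v_case = np.array([np.mean((c > controls) + 0.5 * (c == controls))
                       for c in cases])
    v_ctrl = np.array([np.mean((cases > c) + 0.5 * (cases == c))
                       for c in controls])
    return v_case, v_ctrl


def empirical_auc(cases, controls) -> ROCResult:
    """Empirical (Mann-Whitney) AUC with a DeLong 95% CI.

    AUC is the probability that a random case scores above a random control,
    counting ties one half.  Degenerate groups (no score variation anywhere)
    leave the CI undefined (NaN bounds) but the AUC is still returned.
    """
    cases = np.asarray(cases, dtype=float)
    controls = np.asarray(controls, dtype=float)
    if cases.size == 0 or controls.size == 0:
        raise ValueError("both groups must be non-empty")
    v_case, v_ctrl = _placements(cases, controls)
    auc = float(v_case.mean())
    var = 0.0
    if cases.size > 1:
        var += np.var(v_case, ddof=1) / cases.size
    if controls.size > 1:
        var += np.var(v_ctrl, ddof=1) / controls.size
    if var > 0:
        half = 1.959963984540054 * np.sqrt(var)
        ci_lo, ci_hi = max(0.0, auc - half), min(1.0, auc + half)
    else:
        ci_lo = ci_hi = float("nan")
    fpr, tpr = roc_curve_points(cases, controls)
    return ROCResult(auc=auc, ci_lo=ci_lo, ci_hi=ci_hi, method="empirical",
                     ci_method="delong", fpr=fpr, tpr=tpr)


def binormal_auc(cases, controls, n_boot: int = 2000,
                 seed: int = 0) -> ROCResult:
    """Binormal (parametric) AUC from sample means and SDs, bootstrap 95% CI.

    Assumes each group's scores are normal; requires at least two values per
    group and non-zero pooled variance.
    """
    cases = np.asarray(cases, dtype=float)
    controls = np.asarray(controls, dtype=float)
    if cases.size < 2 or controls.size < 2:
        raise ValueError("binormal AUC needs >= 2 values per group")

    def _auc(ca, co):
        spread = np.hypot(np.std(ca, ddof=1), np.std(co, ddof=1))
        if spread == 0:
            raise ValueError("zero pooled variance: binormal AUC undefined")
        return float(stats.norm.cdf((np.mean(ca) - np.mean(co)) / spread))

    auc = _auc(cases, controls)
    rng = np.random.default_rng(seed)
    boot = []
    for _ in range(n_boot):
        ca = rng.choice(cases, size=cases.size, replace=True)
        co = rng.choice(controls, size=controls.size, replace=True)
        spread = np.hypot(np.std(ca, ddof=1), np.std(co, ddof=1))
        if spread > 0:
            boot.append(stats.norm.cdf((np.mean(ca) - np.mean(co)) / spread))
    ci_lo, ci_hi = (np.quantile(boot, [0.025, 0.975]) if boot
                    else (float("nan"), float("nan")))
    # Smooth binormal curve on a z-grid.
    mu_c, sd_c = np.mean(cases), np.std(cases, ddof=1)
    mu_n, sd_n = np.mean(controls), np.std(controls, ddof=1)
    grid = np.linspace(mu_n - 5 * max(sd_n, 1e-12), mu_c + 5 * max(sd_c, 1e-12), 201)
    fpr = stats.norm.sf((grid - mu_n) / max(sd_n, 1e-12))
    tpr = stats.norm.sf((grid - mu_c) / max(sd_c, 1e-12))
    fpr = np.concatenate([[1.0], fpr, [0.0]])[::-1]
    tpr = np.concatenate([[1.0], tpr, [0.0]])[::-1]
    return ROCResult(auc=auc, ci_lo=float(ci_lo), ci_hi=float(ci_hi),
                     method="binormal", ci_method="bootstrap",
                     fpr=fpr, tpr=tpr)
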