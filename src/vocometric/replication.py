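"""Replication-style Monte-Carlo analyses over simulated cohorts.

Helpers that repeat the full simulate -> score -> fit chain over many seeded
cohorts and summarise the quantities the study design is meant to measure:
how accurately the fitting pipeline recovers a group's mean intelligibility
threshold at the standard 12-digits-per-level design, and how well the
threshold separates a patient group from controls in repeated sampling.
"""

from __future__ import annotations

import numpy as np

from .psychometric import FitOptions, fit_psychometric
from .roc import empirical_auc
from .scoring import aggregate
from .synthetic import (
    GroupSpec,
    build_stimulus_list,
    draw_listener_params,
    simulate_listener,
)

__all__ = ["cohort_threshold_recovery", "threshold_auc_distribution"]


def cohort_threshold_recovery(group: GroupSpec, n_cohorts: int = 20,
                              seed: int = 0, design_seed: int = 0,
                              fit_options: FitOptions | None = None
                              ) -> dict:
    """Simulate and fit ``n_cohorts`` full cohorts of one group.

    Each cohort draws ``group.n`` listeners from the group's parameter
    distributions, simulates the 100-item session for each, fits the
    psychometric model, and records the cohort-mean fitted threshold.
    Returns the grand mean over cohorts, the per-cohort means, and the number
    of listeners fitted.
    """
    design = build_stimulus_list(design_seed)
    root = np.random.SeedSequence(seed)
    cohort_means = []
    n_fitted = 0
    for cohort_seq in root.spawn(n_cohorts):
        thresholds = []
        for listener_seq in cohort_seq.spawn(group.n):
            rng = np.random.default_rng(listener_seq)
            params = draw_listener_params(group, rng)
            trials = simulate_listener(params, design, rng)
            data = aggregate(trials, "P000")
            fit = fit_psychometric(data.x, data.k, data.n, fit_options)
            if fit.threshold_defined:
                thresholds.append(fit.threshold)
                n_fitted += 1
        cohort_means.append(float(np.mean(thresholds)))
    return {
        "grand_mean": float(np.mean(cohort_means)),
        "cohort_means": cohort_means,
        "n_fitted": n_fitted,
    }


def threshold_auc_distribution(case_group: GroupSpec, control_group: GroupSpec,
                               n_cohorts: int = 500, seed: int = 0) -> dict:
    """Mean empirical AUC of the true threshold over repeated cohort draws.

    Each cohort draws thresholds for both groups from their truncated-normal
    population distributions and computes the empirical AUC with higher
    threshold meaning case.  This isolates the discriminability implied by
    the group threshold distributions themselves (no trial simulation or
    curve fitting).
    """
    root = np.random.SeedSequence(seed)
    aucs = []
    for seq in root.spawn(n_cohorts):
        rng = np.random.default_rng(seq)
        cases = [draw_listener_params(case_group, rng).m
                 for _ in range(case_group.n)]
        controls = [draw_listener_params(control_group, rng).m
                    for _ in range(control_group.n)]
        aucs.append(empirical_auc(cases, controls).auc)
    return {"mean_auc": float(np.mean(aucs)), "aucs": aucs}
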