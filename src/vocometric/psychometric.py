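"""Weibull psychometric function with guess/lapse asymptotes and overdispersion.

The probability of identifying a digit at a stimulus level of ``2**x``
vocoding channels is modelled as

    p(x) = gamma + (1 - gamma - lam) * F(x),      F(x) = 1 - exp(-(x/alpha)**beta)

on the log2-channel axis x, where ``gamma`` is the guess rate (floor
performance), ``lam`` the lapse rate (errors at ceiling), and (alpha, beta)
the Weibull scale and shape.  Per-level digit counts are binomial, or
beta-binomial with overdispersion ``eta`` in [0, 1): the latent per-trial
success probability has variance ``eta**2 * p * (1 - p)``, so eta = 0 is the
exact binomial limit.

The quantities reported per listener are the 50% intelligibility threshold in
channels (the absolute 50%-correct point, ``2**x50``), the slope of p at that
point (per log2-channel), gamma, lam and eta.  Fitting is maximum likelihood
with coarse grid initialisation and bounded multi-start local optimisation;
it is deterministic for fixed data and options.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import betaln, gammaln

__all__ = [
    "UndefinedThresholdError",
    "PsychometricFit",
    "FitOptions",
    "predict_pcorrect",
    "neg_log_likelihood",
    "fit_psychometric",
    "threshold_50",
    "slope_at_threshold",
    "weibull_from_threshold_slope",
    "WeibullPsychometric",
]

# Fitting bounds: alpha on the log2-channel axis (log2(48) allows thresholds
# up to twice the largest tested level), beta controls steepness, gamma/lam
# are asymptote rates, eta the overdispersion.
ALPHA_BOUNDS = (0.01, np.log2(48.0))
BETA_BOUNDS = (0.1, 20.0)
RATE_BOUNDS = (0.0, 0.25)
ETA_BOUNDS = (0.0, 0.95)

_P_EPS = 1e-9  # probability guard for mass evaluation
_ETA_BINOMIAL = 1e-8  # below this, use the exact binomial branch


class UndefinedThresholdError(ValueError):
    """The fitted curve never reaches 50% correct (1 - lam <= 0.5)."""


def _weibull_cdf(x, alpha: float, beta: float):
    if alpha <= 0 or beta <= 0:
        raise ValueError(f"alpha and beta must be positive, got ({alpha}, {beta})")
    x = np.asarray(x, dtype=float)
    out = -np.expm1(-np.power(np.maximum(x, 0.0) / alpha, beta))
    return out


def predict_pcorrect(x, alpha: float, beta: float, gamma: float = 0.0,
                     lam: float = 0.0):
    """Probability correct at log2-channel level ``x``.

    Monotone non-decreasing in x, ranging from gamma at x = 0 to 1 - lam as
    x grows.
    """
    return gamma + (1.0 - gamma - lam) * _weibull_cdf(x, alpha, beta)


def neg_log_likelihood(theta, x, k, n) -> float:
    """Negative log-likelihood of per-level counts under the model.

    ``theta = (alpha, beta, gamma, lam, eta)``; ``x`` are log2-channel
    levels, ``k`` successes out of ``n`` digit presentations per level.
    With eta = 0 the per-level mass is Binomial(n, p(x)); otherwise
    Beta-Binomial with mean p(x) and concentration ``nu = 1/eta**2 - 1``
    (shape a = p * nu, b = (1 - p) * nu).
    """
    alpha, beta, gamma, lam, eta = theta
    if not 0.0 <= eta < 1.0:
        raise ValueError(f"eta must lie in [0, 1), got {eta}")
    x = np.asarray(x, dtype=float)
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    p = np.clip(predict_pcorrect(x, alpha, beta, gamma, lam), _P_EPS, 1.0 - _P_EPS)
    log_binom = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    if eta < _ETA_BINOMIAL:
        ll = log_binom + k * np.log(p) + (n - k) * np.log1p(-p)
    else:
        nu = 1.0 / eta**2 - 1.0
        a = p * nu
        b = (1.0 - p) * nu
        ll = log_binom + betaln(k + a, n - k + b) - betaln(a, b)
    return float(-np.sum(ll))


def threshold_50(alpha: float, beta: float, gamma: float = 0.0,
                 lam: float = 0.0) -> float:
    """50% intelligibility threshold in channels (absolute 50% correct).

    Solves gamma + (1 - gamma - lam) * F(x50) = 0.5 and returns 2**x50.
    Raises :class:`UndefinedThresholdError` when the upper asymptote
    1 - lam does not exceed 0.5.
    """
    if 1.0 - lam <= 0.5:
        raise UndefinedThresholdError(
            f"upper asymptote 1 - lam = {1.0 - lam:.3f} never reaches 50% correct"
        )
    if gamma >= 0.5:
        # Curve starts above 50%: threshold collapses to the 1-channel floor.
        return 1.0
    q = (0.5 - gamma) / (1.0 - gamma - lam)
    x50 = alpha * (-np.log1p(-q)) ** (1.0 / beta)
    return float(2.0**x50)


def slope_at_threshold(alpha: float, beta: float, gamma: float = 0.0,
                       lam: float = 0.0) -> float:
    """Slope of p(x) at the 50% point, in proportion per log2-channel."""
    thr = threshold_50(alpha, beta, gamma, lam)
    x50 = np.log2(thr)
    u = (x50 / alpha) ** beta
    dF = (beta / alpha) * (x50 / alpha) ** (beta - 1.0) * np.exp(-u)
    return float((1.0 - gamma - lam) * dF)


def weibull_from_threshold_slope(threshold: float, slope: float,
                                 gamma: float = 0.0, lam: float = 0.0
                                 ) -> tuple[float, float]:
    """Invert (threshold in channels, slope at threshold) to (alpha, beta).

    Used by the listener simulator, whose natural parameters are the
    reported ones.  Requires threshold > 1 channel (x50 > 0) and slope > 0.
    """
    if threshold <= 1.0:
        raise ValueError(f"threshold must exceed 1 channel, got {threshold}")
    if slope <= 0:
        raise ValueError(f"slope must be positive, got {slope}")
    if 1.0 - lam <= 0.5 or gamma >= 0.5:
        raise ValueError("asymptotes incompatible with a defined 50% threshold")
    x50 = np.log2(threshold)
    q = (0.5 - gamma) / (1.0 - gamma - lam)
    u = -np.log1p(-q)  # (x50/alpha)**beta at the threshold point
    beta = slope * x50 / ((1.0 - gamma - lam) * u * (1.0 - q))
    alpha = x50 / u ** (1.0 / beta)
    return float(alpha), float(beta)


@dataclass(frozen=True)
class FitOptions:
    """Optimiser settings: grid resolution, start count, tolerance, bounds."""

    n_grid_alpha: int = 15
    n_grid_beta: int = 9
    n_starts: int = 3
    tol: float = 1e-9
    max_lapse: float = RATE_BOUNDS[1]
    max_guess: float = RATE_BOUNDS[1]
    max_eta: float = ETA_BOUNDS[1]


@dataclass(frozen=True)
class PsychometricFit:
    """Maximum-likelihood fit of the psychometric model for one listener."""

    alpha: float
    beta: float
    gamma: float
    lam: float
    eta: float
    nll: float
    converged: bool
    boundary: bool
    threshold_defined: bool
    threshold: float | None
    slope: float | None


def _threshold_slope(alpha, beta, gamma, lam):
    try:
        thr = threshold_50(alpha, beta, gamma, lam)
    except UndefinedThresholdError:
        return False, None, None
    return True, thr, slope_at_threshold(alpha, beta, gamma, lam)


def fit_psychometric(x, k, n, opts: FitOptions | None = None) -> PsychometricFit:
    """Fit the Weibull/beta-binomial model to per-level counts.

    ``x``: log2-channel levels; ``k``: digits correct; ``n``: digits
    presented per level.  Requires at least four informative levels.  A coarse
    (alpha, beta) grid at eta = 0 seeds bounded L-BFGS-B runs over all five
    parameters; the best optimum is returned.  Non-convergence is flagged,
    never silent, and all-floor / all-ceiling data are flagged as boundary
    fits.
    """
    opts = opts or FitOptions()
    x = np.asarray(x, dtype=float)
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    if not (x.shape == k.shape == n.shape):
        raise ValueError("x, k, n must have matching shapes")
    informative = n > 0
    if informative.sum() < 4:
        raise ValueError("need at least 4 levels with n > 0 to fit 5 parameters")
    x, k, n = x[informative], k[informative], n[informative]
    if np.any(k < 0) or np.any(k > n):
        raise ValueError("counts must satisfy 0 <= k <= n")
    boundary = bool(np.all(k == 0) or np.all(k == n))

    bounds = [
        ALPHA_BOUNDS,
        BETA_BOUNDS,
        (0.0, opts.max_guess),
        (0.0, opts.max_lapse),
        (0.0, opts.max_eta),
    ]

    # Coarse grid over (alpha, beta) with small fixed asymptotes, eta = 0.
    alphas = np.linspace(0.2, ALPHA_BOUNDS[1] - 0.1, opts.n_grid_alpha)
    betas = np.geomspace(0.5, 12.0, opts.n_grid_beta)
    g0, l0 = 0.02, 0.02
    grid = [
        (neg_log_likelihood((a, b, g0, l0, 0.0), x, k, n), a, b)
        for a in alphas
        for b in betas
    ]
    grid.sort(key=lambda t: t[0])

    best = None
    for _, a0, b0 in grid[: opts.n_starts]:
        res = optimize.minimize(
            neg_log_likelihood,
            x0=np.array([a0, b0, g0, l0, 0.0]),
            args=(x, k, n),
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": opts.tol, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    alpha, beta, gamma, lam, eta = best.x
    defined, thr, slope = _threshold_slope(alpha, beta, gamma, lam)
    return PsychometricFit(
        alpha=float(alpha),
        beta=float(beta),
        gamma=float(gamma),
        lam=float(lam),
        eta=float(eta),
        nll=float(best.fun),
        converged=bool(best.success),
        boundary=boundary,
        threshold_defined=defined,
        threshold=thr,
        slope=slope,
    )


class WeibullPsychometric:
    """Estimator interface to the psychometric fit.

    ``fit(X, y, n_trials)`` takes channel counts ``X`` (one per level, > 0),
    digit-correct counts ``y`` and digits presented ``n_trials``; levels are
    transformed to log2 internally.  Fitted attributes carry the reported
    parameters: ``threshold_`` (channels), ``slope_`` (per log2-channel),
    ``gamma_``, ``lam_``, ``eta_``, plus ``nll_`` and ``converged_``.
    """

    def __init__(self, n_grid_alpha: int = 15, n_grid_beta: int = 9,
                 n_starts: int = 3, tol: float = 1e-9,
                 max_lapse: float = RATE_BOUNDS[1],
                 max_guess: float = RATE_BOUNDS[1],
                 max_eta: float = ETA_BOUNDS[1]):
        self.n_grid_alpha = n_grid_alpha
        self.n_grid_beta = n_grid_beta
        self.n_starts = n_starts
        self.tol = tol
        self.max_lapse = max_lapse
        self.max_guess = max_guess
        self.max_eta = max_eta

    _param_names = ("n_grid_alpha", "n_grid_beta", "n_starts", "tol",
                    "max_lapse", "max_guess", "max_eta")

    def get_params(self, deep: bool = True) -> dict:
        return {name: getattr(self, name) for name in self._param_names}

    def set_params(self, **params) -> "WeibullPsychometric":
        for name, value in params.items():
            if name not in self._param_names:
                raise ValueError(f"invalid parameter {name!r} for WeibullPsychometric")
            setattr(self, name, value)
        return self

    def _options(self) -> FitOptions:
        return FitOptions(**self.get_params())

    def fit(self, X, y, n_trials) -> "WeibullPsychometric":
        channels = np.asarray(X, dtype=float).ravel()
        if np.any(channels <= 0):
            raise ValueError("channel counts must be positive")
        fit = fit_psychometric(np.log2(channels), y, n_trials, self._options())
        self.fit_ = fit
        self.alpha_ = fit.alpha
        self.beta_ = fit.beta
        self.gamma_ = fit.gamma
        self.lam_ = fit.lam
        self.eta_ = fit.eta
        self.nll_ = fit.nll
        self.converged_ = fit.converged
        self.threshold_defined_ = fit.threshold_defined
        self.threshold_ = fit.threshold
        self.slope_ = fit.slope
        return self

    def predict(self, X):
        """Predicted proportion of digits correct at channel counts ``X``."""
        if not hasattr(self, "fit_"):
            raise RuntimeError("call fit() before predict()")
        channels = np.asarray(X, dtype=float).ravel()
        return predict_pcorrect(np.log2(channels), self.alpha_, self.beta_,
                                self.gamma_, self.lam_)
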