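"""Ex-Gaussian reaction-time model and Flanker performance summaries.

The ex-Gaussian is the convolution of a Normal(mu, sigma) with an
Exponential(mean tau); its mean is mu + tau and its variance
sigma^2 + tau^2.  Fitting is by maximum likelihood with a
method-of-moments initializer; the log-density uses a log-scaled normal
CDF so it stays finite for large mu/tau ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

from fidgetkit.task import TrialEvent

# responses faster than this are flagged as anticipatory
RT_FLOOR_MS = 100.0


@dataclass(frozen=True)
class ExGaussianParams:
    """(mu, sigma, tau) in ms; mean = mu + tau, var = sigma^2 + tau^2."""

    mu: float
    sigma: float
    tau: float
    n_used: int | None = None
    converged: bool | None = None

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.tau <= 0:
            raise ValueError("sigma and tau must be positive")

    @property
    def mean(self) -> float:
        return self.mu + self.tau

    @property
    def variance(self) -> float:
        return self.sigma**2 + self.tau**2


def exgauss_logpdf(x, mu: float, sigma: float, tau: float) -> np.ndarray:
    """Stable log-density of the ex-Gaussian.

    log f(x) = -log(tau) + sigma^2/(2 tau^2) - (x - mu)/tau
               + log Phi((x - mu)/sigma - sigma/tau)
    using the log-scaled normal CDF (``log_ndtr``), which avoids the
    0 * inf failure of the naive erfc form when sigma/tau is large.
    """
    if sigma <= 0 or tau <= 0:
        raise ValueError("sigma and tau must be positive")
    x = np.asarray(x, dtype=float)
    z = (x - mu) / sigma
    return (
        -np.log(tau)
        + 0.5 * (sigma / tau) ** 2
        - (x - mu) / tau
        + special.log_ndtr(z - sigma / tau)
    )


def exgauss_loglik(params: ExGaussianParams, rts) -> float:
    """Sum of ex-Gaussian log densities; non-finite result signals
    parameter overflow."""
    rts = np.asarray(rts, dtype=float)
    if rts.size == 0:
        raise ValueError("rts must be non-empty")
    return float(np.sum(exgauss_logpdf(rts, params.mu, params.sigma, params.tau)))


def _moments_init(rts: np.ndarray) -> tuple[float, float, float]:
    """Method-of-moments starting point: tau from skewness, then mu and
    sigma from the first two moments."""
    m = float(np.mean(rts))
    v = float(np.var(rts))
    skew = float(stats.skew(rts))
    tau0 = np.cbrt(max(skew, 1e-6) / 2.0) * np.sqrt(v)
    tau0 = float(np.clip(tau0, 1e-3, None))
    sigma0 = float(np.sqrt(max(v - tau0**2, 1e-6)))
    mu0 = m - tau0
    return mu0, sigma0, tau0


def fit_exgaussian(rts, min_n: int = 10) -> ExGaussianParams:
    """Maximum-likelihood ex-Gaussian fit.

    Omissions (``None``/NaN) are excluded before fitting.  Warns when the
    sample has non-positive skewness (the exponential component is then
    weakly identified).  On optimizer failure the moments initializer is
    returned with ``converged=False``.
    """
    rts = np.asarray([r for r in rts if r is not None], dtype=float)
    rts = rts[np.isfinite(rts)]
    if rts.size < min_n:
        raise ValueError(f"need at least {min_n} reaction times, got {rts.size}")
    if stats.skew(rts) <= 0:
        warnings.warn(
            "non-positive skewness: ex-Gaussian tau is weakly identified",
            stacklevel=2,
        )
    mu0, sigma0, tau0 = _moments_init(rts)

    def nll(theta: np.ndarray) -> float:
        mu, log_sigma, log_tau = theta
        ll = np.sum(exgauss_logpdf(rts, mu, np.exp(log_sigma), np.exp(log_tau)))
        return np.inf if not np.isfinite(ll) else -ll

    x0 = np.array([mu0, np.log(sigma0), np.log(tau0)])
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000})
    # the optimizer must never worsen the start
    if res.fun <= nll(x0) and np.isfinite(res.fun):
        mu, sigma, tau = res.x[0], float(np.exp(res.x[1])), float(np.exp(res.x[2]))
        converged = bool(res.success)
    else:
        mu, sigma, tau = mu0, sigma0, tau0
        converged = False
    if not converged:
        warnings.warn("ex-Gaussian fit did not converge; fallback flagged",
                      stacklevel=2)
    return ExGaussianParams(float(mu), sigma, tau, n_used=int(rts.size),
                            converged=converged)


def performance_summary(trials: list[TrialEvent]) -> dict:
    """Counts and percentages of correct / incorrect / omitted trials,
    overall and per trial type.

    correct + incorrect + omissions = total; percentages use the
    relevant denominator times 100.
    """
    idx = [t.trial_index for t in trials]
    if len(set(idx)) != len(idx):
        raise ValueError("duplicate trial indices")
    total = len(trials)
    omissions = sum(t.omitted for t in trials)
    correct = sum(t.correct for t in trials)
    incorrect = total - correct - omissions
    by_type: dict[str, dict] = {}
    for ttype in sorted({t.trial_type for t in trials}):
        sub = [t for t in trials if t.trial_type == ttype]
        n_corr = sum(t.correct for t in sub)
        by_type[ttype] = {
            "n_trials": len(sub),
            "correct": n_corr,
            "percent_correct": 100.0 * n_corr / len(sub),
        }
    return {
        "n_trials": total,
        "correct": correct,
        "incorrect": incorrect,
        "omissions": omissions,
        "percent_correct": 100.0 * correct / total,
        "by_type": by_type,
        "anticipatory": sum(
            1 for t in trials if t.rt_ms is not None and t.rt_ms < RT_FLOOR_MS
        ),
    }
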