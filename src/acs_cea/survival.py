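"""Weibull event-time models with right censoring.

The first-year event probabilities and the extrapolated second-year
conditional probabilities both derive from a Weibull survival model
``S(t) = exp(-(t/lambda)^k)``.  Two routes produce a fit:

* :func:`fit_weibull_mle` — maximum likelihood on right-censored
  individual patient data, endpoint-wise (competing endpoints are treated
  as censored), with the observed-information covariance on
  (log k, log lambda);
* :func:`calibrate_from_probs` — exact inversion of a printed pair
  (first-year probability, conditional second-year probability), the only
  anchors available when no patient-level data exist.

The Markov model consumes :func:`conditional_annual_prob` at year 2 and
holds it constant for all later years.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "WeibullFit",
    "FittingError",
    "fit_weibull_mle",
    "survival_at",
    "conditional_annual_prob",
    "calibrate_from_probs",
]


class FittingError(RuntimeError):
    """Raised when maximum-likelihood estimation cannot proceed or converge."""


@dataclass(frozen=True)
class WeibullFit:
    """Fitted Weibull shape/scale with log-parameter covariance.

    ``cov_log`` is the 2x2 covariance of (log shape, log scale) from the
    observed information at the optimum; calibrated (non-fitted) instances
    carry a zero matrix.
    """

    shape: float
    scale: float
    cov_log: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))
    n_events: int = 0
    n_censored: int = 0

    def __post_init__(self) -> None:
        if not (self.shape > 0 and self.scale > 0):
            raise ValueError("shape and scale must be positive")
        cov = np.asarray(self.cov_log, dtype=float)
        if cov.shape != (2, 2) or not np.allclose(cov, cov.T, atol=1e-8):
            raise ValueError("cov_log must be a symmetric 2x2 matrix")
        if np.any(np.linalg.eigvalsh((cov + cov.T) / 2) < -1e-10):
            raise ValueError("cov_log must be positive semi-definite")
        object.__setattr__(self, "cov_log", cov)


def survival_at(fit: WeibullFit, t: float | np.ndarray) -> float | np.ndarray:
    """Survival function ``exp(-(t/scale)^shape)``; ``t`` in years, >= 0."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    s = np.exp(-((t / fit.scale) ** fit.shape))
    return float(s) if s.ndim == 0 else s


def conditional_annual_prob(fit: WeibullFit, year: int) -> float:
    """Probability of the event during ``year`` given event-free entry.

    ``(S(year-1) - S(year)) / S(year-1)``; year 1 reduces to ``1 - S(1)``.
    The cohort model uses year 2 and holds it constant afterwards.
    """
    if year < 1:
        raise ValueError("year must be >= 1")
    s_prev = survival_at(fit, float(year - 1))
    if s_prev == 0.0:
        raise ZeroDivisionError(f"S({year - 1}) = 0; conditional probability undefined")
    return float((s_prev - survival_at(fit, float(year))) / s_prev)


def calibrate_from_probs(p_year1: float, p_year2_conditional: float) -> WeibullFit:
    """Unique Weibull matching a first-year and a conditional second-year probability.

    Solves ``1 - S(1) = p1`` and ``(S(1) - S(2))/S(1) = p2`` through the
    closed relation ``2^k - 1 = ln(1 - p2) / ln(1 - p1)``; equal
    probabilities give the exponential case ``k = 1`` exactly.  The returned
    fit carries zero covariance (it encodes printed values, not sampling
    noise).
    """
    for name, p in (("p_year1", p_year1), ("p_year2_conditional", p_year2_conditional)):
        if not 0.0 < p < 1.0:
            raise ValueError(f"{name} must lie strictly inside (0, 1), got {p}")
    ratio = math.log1p(-p_year2_conditional) / math.log1p(-p_year1)
    k = math.log2(1.0 + ratio)
    if not (k > 0 and math.isfinite(k)):
        raise ValueError(
            f"infeasible probability pair ({p_year1}, {p_year2_conditional})"
        )
    lam = (-math.log1p(-p_year1)) ** (-1.0 / k)
    return WeibullFit(shape=k, scale=lam)


def _neg_loglik_and_grad(
    theta: np.ndarray, t: np.ndarray, d: np.ndarray
) -> tuple[float, np.ndarray]:
    """Negative log-likelihood in (log k, log lambda) and its gradient.

    ``d`` is 1 for events, 0 for right-censored times.
    """
    log_k, log_lam = theta
    k = math.exp(log_k)
    log_t = np.log(t)
    z = k * (log_t - log_lam)  # log (t/lam)^k
    ez = np.exp(z)
    n_ev = d.sum()
    ll = np.sum(d * (log_k + z - log_t)) - np.sum(ez)
    # d ll / d log_k  (chain rule through k)
    dll_dlogk = n_ev + np.sum((d - ez) * z)
    dll_dloglam = -k * n_ev + k * np.sum(ez)
    return -ll, -np.array([dll_dlogk, dll_dloglam])


def fit_weibull_mle(
    ipd: Iterable,
    endpoint: str,
    *,
    arm: str | None = None,
    max_iter: int = 500,
    gtol: float = 1e-8,
) -> WeibullFit:
    """Endpoint-wise Weibull MLE on right-censored patient records.

    ``ipd`` is an iterable of records with attributes ``arm``, ``time`` and
    ``event`` (see :mod:`acs_cea.synthetic`); records whose ``event`` differs
    from ``endpoint`` — other endpoints as well as administrative censoring —
    enter the likelihood as right-censored at their recorded time.  Requires
    at least two events.
    """
    times: list[float] = []
    events: list[float] = []
    for rec in ipd:
        if arm is not None and rec.arm != arm:
            continue
        if rec.time <= 0:
            raise ValueError("all times must be positive")
        times.append(rec.time)
        events.append(1.0 if rec.event == endpoint else 0.0)
    t = np.asarray(times)
    d = np.asarray(events)
    n_events = int(d.sum())
    if n_events < 2:
        raise FittingError(
            f"need at least 2 events of kind {endpoint!r}, found {n_events}"
        )
    # exponential start: scale = total exposure / events, shape = 1
    theta0 = np.array([0.0, math.log(t.sum() / n_events)])
    res = optimize.minimize(
        _neg_loglik_and_grad,
        theta0,
        args=(t, d),
        jac=True,
        method="BFGS",
        options={"maxiter": max_iter, "gtol": gtol},
    )
    grad_norm = float(np.linalg.norm(res.jac))
    if not res.success and grad_norm > 1e-4:
        raise FittingError(
            f"Weibull MLE did not converge for endpoint {endpoint!r}: "
            f"{res.message} (iterations={res.nit}, |grad|={grad_norm:.2e})"
        )
    # observed information: central-difference Hessian of the negative log-lik
    hess = _numerical_hessian(lambda th: _neg_loglik_and_grad(th, t, d)[0], res.x)
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(hess)
    cov = (cov + cov.T) / 2.0
    if np.any(np.linalg.eigvalsh(cov) < 0):
        cov = np.zeros((2, 2))
    return WeibullFit(
        shape=math.exp(res.x[0]),
        scale=math.exp(res.x[1]),
        cov_log=cov,
        n_events=n_events,
        n_censored=len(t) - n_events,
    )


def _numerical_hessian(f, x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    n = len(x)
    hess = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            xpp = x.copy(); xpp[i] += eps; xpp[j] += eps
            xpm = x.copy(); xpm[i] += eps; xpm[j] -= eps
            xmp = x.copy(); xmp[i] -= eps; xmp[j] += eps
            xmm = x.copy(); xmm[i] -= eps; xmm[j] -= eps
            hess[i, j] = hess[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * eps**2)
    del f0
    return hess


def loglik(fit: WeibullFit, times: Sequence[float], events: Sequence[float]) -> float:
    """Log-likelihood of right-censored data under a given fit (for diagnostics)."""
    theta = np.array([math.log(fit.shape), math.log(fit.scale)])
    nll, _ = _neg_loglik_and_grad(theta, np.asarray(times, float), np.asarray(events, float))
    return -nll
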