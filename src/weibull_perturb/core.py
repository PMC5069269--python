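"""Weibull distribution primitives and the reduced log-likelihood.

The two-parameter Weibull distribution ``W(alpha, beta)`` has density

    f(t) = (beta t^(beta-1) / alpha^beta) exp(-(t/alpha)^beta),  t > 0,

with scale ``alpha > 0`` (time units) and shape ``beta > 0``
(dimensionless).  For a right-censored sample ``(t_k, delta_k)`` —
``delta_k = 1`` for an observed failure, ``0`` for a unit still alive at
``t_k`` — the log-likelihood, after profiling out constants, reduces to a
function of two data summaries:

    ln tau      = (1/n) sum_k delta_k ln t_k        (mean log failure time)
    theta(beta) = ((1/n) sum_k t_k^beta)^(1/beta)   (sum over ALL N times)

where ``n`` is the failure count.  The scale MLE is the closed form
``alpha* = theta(beta*)``; everything difficult lives in the shape
equation, handled in :mod:`weibull_perturb.perturbation` and
:mod:`weibull_perturb.diagnostics`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from scipy.stats import weibull_min

__all__ = [
    "DegenerateSampleError",
    "EstimationError",
    "LifetimeSample",
    "WeibullParams",
    "pdf",
    "cdf",
    "quantile",
    "log_tau",
    "theta",
    "reduced_log_likelihood",
]


class DegenerateSampleError(ValueError):
    """The sample cannot support Weibull shape estimation.

    Raised when there are no observed failures, fewer than two records,
    or every failure sits at the sample maximum (the pivot shape estimate
    is then undefined).
    """


class EstimationError(RuntimeError):
    """An estimator failed to produce finite, valid parameters."""


@dataclass(frozen=True)
class LifetimeSample:
    """An ordered right-censored lifetime sample.

    Parameters
    ----------
    times
        Positive lifetimes; stored sorted nondecreasing.  Unsorted input
        is sorted on construction, carrying each event flag with its time.
    events
        Per-time indicator: 1 = observed failure, 0 = right-censored.

    Notes
    -----
    Construction enforces the conditions the estimators need: N >= 2, at
    least one failure, at least one time strictly below the maximum, and
    at least one failure strictly below the maximum (otherwise the pivot
    shape estimate beta_1 is undefined).
    """

    times: np.ndarray
    events: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        d = np.asarray(self.events)
        if t.ndim != 1 or d.shape != t.shape:
            raise ValueError("times and events must be 1-d arrays of equal length")
        if t.size < 2:
            raise DegenerateSampleError("need at least two records")
        if not np.all(np.isfinite(t)) or np.any(t <= 0):
            raise ValueError("all times must be positive and finite")
        if not np.isin(d, (0, 1)).all():
            raise ValueError("events must be 0 (censored) or 1 (failure)")
        order = np.argsort(t, kind="stable")
        t = t[order]
        d = d[order].astype(np.int64)
        if d.sum() < 1:
            raise DegenerateSampleError("sample contains no observed failures")
        if t[0] == t[-1]:
            raise DegenerateSampleError(
                "all times identical: need at least one time below the maximum"
            )
        if np.all(t[d == 1] == t[-1]):
            raise DegenerateSampleError(
                "every failure occurs at the sample maximum; "
                "the pivot shape estimate is undefined"
            )
        t.setflags(write=False)
        d.setflags(write=False)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "events", d)

    @property
    def N(self) -> int:
        """Total number of records."""
        return int(self.times.size)

    @property
    def n(self) -> int:
        """Number of observed failures."""
        return int(self.events.sum())

    @property
    def censoring_rate(self) -> float:
        """Fraction of censored records, (N - n) / N."""
        return 1.0 - self.n / self.N

    @property
    def t_max(self) -> float:
        """Largest recorded time t_N."""
        return float(self.times[-1])


@dataclass(frozen=True)
class WeibullParams:
    """Weibull scale ``alpha`` (time units) and shape ``beta``."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.alpha) and self.alpha > 0):
            raise ValueError(f"alpha must be positive and finite, got {self.alpha}")
        if not (np.isfinite(self.beta) and self.beta > 0):
            raise ValueError(f"beta must be positive and finite, got {self.beta}")


def _frozen(params: WeibullParams):
    return weibull_min(params.beta, scale=params.alpha)


def pdf(t, params: WeibullParams):
    """Weibull density at ``t > 0``."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("pdf requires t > 0")
    return _frozen(params).pdf(t)


def cdf(t, params: WeibullParams):
    """Failure probability F(t) = 1 - exp(-(t/alpha)^beta) for ``t >= 0``."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("cdf requires t >= 0")
    return _frozen(params).cdf(t)


def quantile(p, params: WeibullParams):
    """Inverse CDF: alpha * (-ln(1 - p))^(1/beta).

    ``p = 1`` returns ``inf`` — the "no censoring" sentinel used by the
    simulation design (censoring rate 0).
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("quantile requires p in [0, 1]")
    return _frozen(params).ppf(p)


def log_tau(sample: LifetimeSample) -> float:
    """Mean log failure time, ln tau = (1/n) sum delta_k ln t_k."""
    return float(np.sum(sample.events * np.log(sample.times)) / sample.n)


def theta(sample: LifetimeSample, beta: float) -> float:
    """Profile scale theta(beta) = ((1/n) sum_k t_k^beta)^(1/beta).

    The sum runs over all N times, failed and censored alike, while the
    divisor is the failure count n.  Evaluated through log-sum-exp so that
    large shapes (t_max^beta far beyond float range) stay finite.
    """
    if not (np.isfinite(beta) and beta > 0):
        raise ValueError(f"beta must be positive and finite, got {beta}")
    log_t = np.log(sample.times)
    return float(np.exp((logsumexp(beta * log_t) - np.log(sample.n)) / beta))


def reduced_log_likelihood(sample: LifetimeSample, params: WeibullParams) -> float:
    """Reduced censored-data objective (theta(beta)/alpha)^beta + beta ln(alpha/tau) - ln beta.

    A monotone recast of the Weibull log-likelihood with constant terms
    dropped: only its stationary point matters, which coincides with the
    MLE ``(theta(beta*), beta*)``.  The absolute value carries no meaning.
    """
    th = theta(sample, params.beta)
    return float(
        (th / params.alpha) ** params.beta
        + params.beta * (np.log(params.alpha) - log_tau(sample))
        - np.log(params.beta)
    )
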