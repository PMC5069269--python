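"""Shape-equation diagnostics and the Newton-Raphson reference solver.

On the normalized scale ``x_k = (t_k/t_N)^(beta_1)``, ``zeta = beta/beta_1``,
the censored-data shape equation reads ``Z(zeta) = 0`` with

    Z(zeta) = 1 - 1/zeta + r(zeta),
    r(zeta) = sum_k (ln x_k) x_k^zeta / sum_k x_k^zeta.

``r`` is a weighted mean of ``ln x_k <= 0``: it increases monotonically
from ``(1/N) sum ln x_k`` (zeta -> 0+) to ``0`` (zeta -> +inf), so ``Z``
is continuous and strictly increasing whenever some ``x_k < 1``, crossing
zero exactly once.  That root ``zeta*`` always exceeds 1, and when
``1 + r(1) > 0`` it is bracketed by ``1 + r(1) < 1/zeta* < 1``.

The Newton-Raphson solver iterates the same equation on the ``beta``
scale and serves as the iterative reference the closed-form series
estimate is judged against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import EstimationError, LifetimeSample, WeibullParams, theta
from .perturbation import NormalizedSample, fit as _perturbative_fit, normalize

__all__ = [
    "ZetaBounds",
    "NewtonRaphsonFit",
    "r_func",
    "r_derivative",
    "Z_func",
    "zeta_bounds",
    "newton_raphson_fit",
]


@dataclass(frozen=True)
class ZetaBounds:
    """Bracket for 1/zeta*: (lower_inv, 1).

    ``lower_inv = max(1 + r(1), 0)``.  When ``1 + r(1) <= 0`` the bracket
    degenerates to the uninformative ``zeta* in (1, inf)`` and
    ``informative`` is False.
    """

    lower_inv: float
    upper_inv: float
    informative: bool

    def contains_zeta(self, zeta: float) -> bool:
        """True if zeta lies in the bracket (strict at informative ends)."""
        inv = 1.0 / zeta
        return self.lower_inv < inv < self.upper_inv


def _log_weights(norm: NormalizedSample, zeta: float) -> np.ndarray:
    """Normalized weights x_k^zeta / sum x_j^zeta, computed in log space."""
    logx = np.log(norm.x)
    a = zeta * logx
    a -= a.max()
    w = np.exp(a)
    return w / w.sum()


def r_func(norm: NormalizedSample, zeta: float) -> float:
    """r(zeta): the x^zeta-weighted mean of ln x_k.  Nonpositive."""
    if zeta <= 0:
        raise ValueError("zeta must be positive")
    w = _log_weights(norm, zeta)
    return float(w @ np.log(norm.x))


def r_derivative(norm: NormalizedSample, zeta: float) -> float:
    """dr/dzeta: the x^zeta-weighted variance of ln x_k.  Nonnegative."""
    if zeta <= 0:
        raise ValueError("zeta must be positive")
    w = _log_weights(norm, zeta)
    u = np.log(norm.x)
    mean = float(w @ u)
    return float(w @ (u - mean) ** 2)


def Z_func(norm: NormalizedSample, zeta: float) -> float:
    """The shape-equation score Z(zeta) = 1 - 1/zeta + r(zeta)."""
    if zeta <= 0:
        raise ValueError("zeta must be positive")
    return 1.0 - 1.0 / zeta + r_func(norm, zeta)


def zeta_bounds(norm: NormalizedSample) -> ZetaBounds:
    """Bracket for the root zeta* from the value of r at zeta = 1."""
    r1 = r_func(norm, 1.0)
    lower = 1.0 + r1
    informative = lower > 0.0
    return ZetaBounds(
        lower_inv=max(lower, 0.0), upper_inv=1.0, informative=informative
    )


@dataclass(frozen=True)
class NewtonRaphsonFit:
    """Iterative reference solution of the shape equation."""

    params: WeibullParams
    iterations: int
    beta0: float
    tol: float


def newton_raphson_fit(
    sample: LifetimeSample,
    beta0: float | None = None,
    tol: float = 1e-3,
    max_iter: int = 100,
) -> NewtonRaphsonFit:
    """Newton-Raphson solution of the shape equation, then alpha = theta(beta).

    Iterates beta <- beta - g(beta)/g'(beta) on

        g(beta) = 1/beta_1 - 1/beta - sum_k ln(t_N/t_k) t_k^beta / sum_k t_k^beta

    whose derivative is 1/beta^2 plus the t^beta-weighted variance of
    ln t_k (strictly positive, so every step is well defined).  Stops when
    the absolute parameter update falls below ``tol``.

    Parameters
    ----------
    beta0
        Starting shape.  Default: the closed-form perturbative estimate
        rounded up to the next integer — a starting value already within
        one unit of the root.
    tol
        Absolute tolerance on the beta update (default 0.001).
    """
    if beta0 is None:
        beta0 = float(np.ceil(_perturbative_fit(sample).params.beta))
    if beta0 <= 0:
        raise ValueError("beta0 must be positive")
    if tol <= 0:
        raise ValueError("tol must be positive")

    log_t = np.log(sample.times)
    c = np.log(sample.t_max) - log_t  # ln(t_N / t_k) >= 0
    inv_beta1 = float(np.sum(sample.events * c) / sample.n)

    b = float(beta0)
    for iteration in range(1, max_iter + 1):
        a = b * log_t
        a -= a.max()
        w = np.exp(a)
        w /= w.sum()
        mean_c = float(w @ c)
        mean_lt = float(w @ log_t)
        var_lt = float(w @ (log_t - mean_lt) ** 2)
        g = inv_beta1 - 1.0 / b - mean_c
        g_prime = 1.0 / (b * b) + var_lt
        step = g / g_prime
        b -= step
        if b <= 0:
            raise EstimationError(
                f"Newton-Raphson left the parameter domain at iteration {iteration}"
            )
        if abs(step) < tol:
            return NewtonRaphsonFit(
                params=WeibullParams(alpha=theta(sample, b), beta=b),
                iterations=iteration,
                beta0=beta0,
                tol=tol,
            )
    raise EstimationError(
        f"Newton-Raphson did not converge in {max_iter} iterations "
        f"(last beta = {b:.6g})"
    )
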