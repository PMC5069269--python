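"""Reading and writing lifetime data, and the serializable fit report."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import LifetimeSample, WeibullParams
from .diagnostics import NewtonRaphsonFit, zeta_bounds
from .perturbation import PerturbativeFit

__all__ = ["LifetimeFormatError", "read_lifetimes", "write_lifetimes", "FitReport"]


class LifetimeFormatError(ValueError):
    """The input file does not conform to the `time,event` CSV contract."""


def read_lifetimes(path) -> LifetimeSample:
    """Read a `time,event` CSV into a validated, sorted LifetimeSample.

    The header is mandatory; `time` must parse as positive reals and
    `event` as 0/1 flags.  Errors name the offending row (1-based data
    rows, excluding the header).
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise LifetimeFormatError(f"{path}: {exc}") from exc
    missing = {"time", "event"} - set(frame.columns)
    if missing:
        raise LifetimeFormatError(
            f"{path}: missing required column(s) {sorted(missing)}"
        )
    times = pd.to_numeric(frame["time"], errors="coerce")
    events = pd.to_numeric(frame["event"], errors="coerce")
    bad_t = np.flatnonzero(~np.isfinite(times) | (times <= 0))
    if bad_t.size:
        raise LifetimeFormatError(
            f"{path}: row {bad_t[0] + 1}: time must be a positive real, "
            f"got {frame['time'].iloc[bad_t[0]]!r}"
        )
    bad_e = np.flatnonzero(~events.isin((0, 1)))
    if bad_e.size:
        raise LifetimeFormatError(
            f"{path}: row {bad_e[0] + 1}: event must be 0 or 1, "
            f"got {frame['event'].iloc[bad_e[0]]!r}"
        )
    return LifetimeSample(
        times=times.to_numpy(float), events=events.to_numpy(np.int64)
    )


def write_lifetimes(sample: LifetimeSample, path) -> None:
    """Write a LifetimeSample as a `time,event` CSV (round-trips exactly)."""
    pd.DataFrame({"time": sample.times, "event": sample.events}).to_csv(
        path, index=False
    )


@dataclass(frozen=True)
class FitReport:
    """A fit plus its diagnostics, serializable to JSON and plain text."""

    alpha: float
    beta: float
    method: str
    N: int
    n: int
    censoring_rate: float
    order: int | None = None
    beta1: float | None = None
    sigma: tuple | None = None
    xi: tuple | None = None
    zeta_star: float | None = None
    bounds: tuple | None = None
    iterations: int | None = None
    warnings: tuple = ()

    @classmethod
    def from_perturbative(cls, sample: LifetimeSample, fit: PerturbativeFit) -> "FitReport":
        b = zeta_bounds(fit.normalized)
        return cls(
            alpha=fit.params.alpha,
            beta=fit.params.beta,
            method="perturbative",
            N=sample.N,
            n=sample.n,
            censoring_rate=sample.censoring_rate,
            order=fit.solution.order,
            beta1=fit.beta1,
            sigma=tuple(fit.sigmas.sigma.tolist()),
            xi=tuple(fit.solution.xi.tolist()),
            zeta_star=fit.solution.zeta_star,
            bounds=(b.lower_inv, b.upper_inv),
            warnings=tuple(fit.warnings),
        )

    @classmethod
    def from_newton_raphson(cls, sample: LifetimeSample, fit: NewtonRaphsonFit) -> "FitReport":
        return cls(
            alpha=fit.params.alpha,
            beta=fit.params.beta,
            method="nr",
            N=sample.N,
            n=sample.n,
            censoring_rate=sample.censoring_rate,
            iterations=fit.iterations,
        )

    @classmethod
    def from_params(
        cls, sample: LifetimeSample, params: WeibullParams, method: str
    ) -> "FitReport":
        return cls(
            alpha=params.alpha,
            beta=params.beta,
            method=method,
            N=sample.N,
            n=sample.n,
            censoring_rate=sample.censoring_rate,
        )

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "FitReport":
        data = json.loads(text)
        for key in ("sigma", "xi", "bounds", "warnings"):
            if data.get(key) is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_text(self) -> str:
        lines = [
            f"method: {self.method}",
            f"alpha:  {self.alpha:.6g}",
            f"beta:   {self.beta:.6g}",
            f"sample: N={self.N}, n={self.n}, censoring rate {self.censoring_rate:.1%}",
        ]
        if self.beta1 is not None:
            lines.append(f"beta1:  {self.beta1:.6g}   zeta*: {self.zeta_star:.6g}")
        if self.sigma is not None:
            lines.append("sigma:  " + ", ".join(f"{s:.4f}" for s in self.sigma))
        if self.iterations is not None:
            lines.append(f"iterations: {self.iterations}")
        for w in self.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines)
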