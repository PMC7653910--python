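"""Domain types and parameter validation shared by every seirtime module.

The package works with population *fractions* of the classic compartmental
models: susceptible S, exposed E (infected, not yet infectious), infectious I
and recovered R.  The SIR model is treated throughout as the special case of
the SEIR model in which the incubation stage is instantaneous; this is
encoded by the sentinel incubation rate ``sigma = inf`` (incubation period
D' = 1/sigma = 0), for which the time-stretch factor ``alpha`` equals 1.

Units: all rates are per day and all times are in days.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SIR_SENTINEL",
    "ParameterError",
    "DomainError",
    "QuadratureError",
    "PeakTruncationError",
    "EpidemicParameters",
    "Trajectory",
    "PeakSummary",
    "QuadratureResult",
    "QuadratureConfig",
    "alpha",
    "make_parameters",
]

#: Sentinel incubation rate meaning "no exposed stage" (the SIR limit).
SIR_SENTINEL: float = math.inf


class ParameterError(ValueError):
    """A model parameter violates its invariant."""


class DomainError(ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class QuadratureError(RuntimeError):
    """A semi-analytic time integral did not reach the requested accuracy."""

    def __init__(self, message: str, achieved: float = math.nan):
        super().__init__(message)
        self.achieved = achieved


class PeakTruncationError(RuntimeError):
    """A trajectory ended while the tracked compartment was still rising."""


def alpha(sigma: float, gamma: float) -> float:
    """Time-stretch factor ``alpha = sigma / (sigma + gamma)``.

    SEIR solution curves are, to good approximation, SIR curves stretched in
    time by ``1/alpha = 1 + D'/D`` where ``D' = 1/sigma`` is the incubation
    period and ``D = 1/gamma`` the infectious period.  The SIR limit
    (``sigma = inf``, i.e. ``D' = 0``) gives exactly 1.

    Parameters
    ----------
    sigma : incubation rate, per day (``inf`` for the SIR limit).
    gamma : recovery rate, per day.
    """
    if not (gamma > 0) or not math.isfinite(gamma):
        raise ParameterError(f"gamma must be a positive finite rate, got {gamma}")
    if not (sigma > 0):
        raise ParameterError(f"sigma must be positive (or inf for SIR), got {sigma}")
    if math.isinf(sigma):
        return 1.0
    return sigma / (sigma + gamma)


@dataclass(frozen=True)
class EpidemicParameters:
    """One SEIR (or SIR, via the sigma sentinel) model instance.

    Attributes
    ----------
    r0_basic : basic reproduction number, dimensionless, > 0.
    gamma : recovery rate per day; infectious period D = 1/gamma.
    sigma : incubation rate per day; ``inf`` selects the SIR limit.
    i0 : initial infectious fraction, in (0, 1).
    e0 : initial exposed fraction, in [0, 1).
    s0 : initial susceptible fraction, derived as 1 - i0 - e0 (the initial
        recovered fraction is always 0).
    """

    r0_basic: float
    gamma: float
    sigma: float
    i0: float
    e0: float = 0.0
    s0: float = field(init=False)

    def __post_init__(self):
        if not (self.r0_basic > 0) or not math.isfinite(self.r0_basic):
            raise ParameterError(f"r0_basic must be > 0, got {self.r0_basic}")
        if not (self.gamma > 0) or not math.isfinite(self.gamma):
            raise ParameterError(f"gamma must be > 0, got {self.gamma}")
        if not (self.sigma > 0):
            raise ParameterError(f"sigma must be > 0 or inf, got {self.sigma}")
        if not (0 < self.i0 < 1):
            raise ParameterError(f"i0 must lie in (0, 1), got {self.i0}")
        if not (0 <= self.e0 < 1):
            raise ParameterError(f"e0 must lie in [0, 1), got {self.e0}")
        if self.i0 + self.e0 >= 1:
            raise ParameterError(
                f"i0 + e0 = {self.i0 + self.e0} must be < 1 so that s0 > 0"
            )
        if self.is_sir and self.e0 != 0:
            raise ParameterError("the SIR limit (sigma=inf) requires e0 = 0")
        object.__setattr__(self, "s0", 1.0 - self.i0 - self.e0)

    # -- derived quantities -------------------------------------------------
    @property
    def beta(self) -> float:
        """Transmission rate beta = r0_basic * gamma, per day."""
        return self.r0_basic * self.gamma

    @property
    def alpha(self) -> float:
        """Stretch factor sigma/(sigma+gamma); 1 in the SIR limit."""
        return alpha(self.sigma, self.gamma)

    @property
    def is_sir(self) -> bool:
        return math.isinf(self.sigma)

    @property
    def d_inf(self) -> float:
        """Infectious period D = 1/gamma, days."""
        return 1.0 / self.gamma

    @property
    def d_inc(self) -> float:
        """Incubation period D' = 1/sigma, days (0 in the SIR limit)."""
        return 0.0 if self.is_sir else 1.0 / self.sigma

    def replace(self, **kwargs) -> "EpidemicParameters":
        vals = dict(
            r0_basic=self.r0_basic, gamma=self.gamma, sigma=self.sigma,
            i0=self.i0, e0=self.e0,
        )
        vals.update(kwargs)
        return EpidemicParameters(**vals)


def make_parameters(
    r0_basic: float,
    gamma: float,
    sigma: float | None = None,
    i0: float = 1e-4,
    e0: float = 0.0,
) -> EpidemicParameters:
    """Build a validated parameter set; ``sigma=None`` selects the SIR limit."""
    return EpidemicParameters(
        r0_basic=float(r0_basic),
        gamma=float(gamma),
        sigma=SIR_SENTINEL if sigma is None else float(sigma),
        i0=float(i0),
        e0=float(e0),
    )


@dataclass
class Trajectory:
    """Compartment fractions on a strictly increasing time grid (days).

    ``e`` is identically zero for SIR runs.  ``s+e+i+r`` is 1 at every point
    up to solver tolerance.
    """

    times: np.ndarray
    s: np.ndarray
    e: np.ndarray
    i: np.ndarray
    r: np.ndarray
    #: optional continuous evaluator t -> (s, e, i, r); set by the ODE
    #: integrator from its dense output, None for reconstructed trajectories
    dense: object = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        for name in ("s", "e", "i", "r"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.times.shape:
                raise ValueError(f"{name} and times must have the same shape")
            setattr(self, name, arr)
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def compartment(self, name: str) -> np.ndarray:
        name = name.lower()
        if name not in ("s", "e", "i", "r"):
            raise KeyError(f"unknown compartment {name!r}")
        return getattr(self, name)

    def conservation_defect(self) -> float:
        """Max absolute deviation of s+e+i+r from 1."""
        return float(np.max(np.abs(self.s + self.e + self.i + self.r - 1.0)))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"t": self.times, "S": self.s, "E": self.e, "I": self.i, "R": self.r}
        )

    def write_csv(self, path) -> None:
        """Write as CSV with header ``t,S,E,I,R`` (LF endings, '.' decimal)."""
        self.to_frame().to_csv(path, index=False, lineterminator="\n")


@dataclass(frozen=True)
class PeakSummary:
    """Timing and height of the infectious maximum.

    ``scaled_delta_t`` is the dimensionless ``alpha * gamma * delta_t`` (for
    SIR, ``gamma * delta_t``), the approximately universal timescale that
    depends only on the basic reproduction number and the initial infectious
    fraction.
    """

    delta_t: float
    i_peak: float
    scaled_delta_t: float


@dataclass(frozen=True)
class QuadratureResult:
    """Value and absolute-error estimate of a semi-analytic time integral."""

    value: float
    abs_error_estimate: float


@dataclass(frozen=True)
class QuadratureConfig:
    """Error control for the adaptive quadrature of the t(S) integrals."""

    abs_tol: float = 1e-10
    rel_tol: float = 1e-10
    limit: int = 200
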