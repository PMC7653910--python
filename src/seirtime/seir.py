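"""Approximate semi-analytic solution of the SEIR model.

Adding an exposed compartment destroys the exact reduction that solves the
SIR model, but setting the third time derivative of R to zero restores a
Bernoulli equation whose solution carries a single new constant, the stretch
factor ``alpha = sigma/(sigma+gamma)``:

    E(S) = 1 - I0 - alpha*S0 + (alpha-1) * [S - (gamma/beta) ln(S/S0)],
    I(S) = I0 - alpha*(S - S0) + (alpha*gamma/beta) ln(S/S0),
    R(S) = (gamma/beta) ln(S0/S)                    (exact, as in SIR),

    t - t0 = int_{S0}^{S} ds / ( s { beta [ -I0 + alpha (s - S0) ]
                                     - alpha gamma ln(s/S0) } ).

With alpha = 1 every formula reduces exactly to its SIR counterpart.  The
closed forms conserve S+E+I+R = 1 identically; their error relative to the
true SEIR ODE solution is the R'''=0 approximation error, which grows as the
incubation stage lengthens (alpha decreases).

Factoring alpha*gamma out of the peak-time quadrature shows that the
dimensionless ``alpha*gamma*dt`` depends (approximately) only on r0_basic
and I0 — the universal timescale the ensemble experiments verify.
"""

from __future__ import annotations

import math

import numpy as np

from . import _semianalytic as _sa
from .core import (
    EpidemicParameters,
    ParameterError,
    PeakSummary,
    QuadratureConfig,
    QuadratureResult,
    Trajectory,
)

__all__ = [
    "seir_exposed_of_s",
    "seir_infectious_of_s",
    "seir_recovered_of_s",
    "seir_time_of_s",
    "seir_peak_time_scaled",
    "seir_early_time",
    "seir_growth_rate",
    "seir_r0_from_growth",
    "seir_r0_exact_from_growth",
    "seir_growth_rate_exact",
    "seir_trajectory",
]


def seir_exposed_of_s(S, params: EpidemicParameters):
    """Exposed fraction E at susceptible fraction S (R'''=0 closed form)."""
    return _sa.exposed_of_s(S, params, params.alpha)


def seir_infectious_of_s(S, params: EpidemicParameters):
    """Infectious fraction I at susceptible fraction S (R'''=0 closed form)."""
    return _sa.infectious_of_s(S, params, params.alpha)


def seir_recovered_of_s(S, params: EpidemicParameters):
    """Recovered fraction R = (gamma/beta) ln(S0/S); exact for SEIR too."""
    return _sa.recovered_of_s(S, params)


def seir_time_of_s(
    S: float, params: EpidemicParameters, quad: QuadratureConfig | None = None
) -> QuadratureResult:
    """Days until the susceptible fraction reaches S (approximate for SEIR)."""
    return _sa.time_of_s(S, params, params.alpha, quad)


def seir_peak_time_scaled(
    params: EpidemicParameters, quad: QuadratureConfig | None = None
) -> PeakSummary:
    """Semi-analytic peak timing with the dimensionless alpha*gamma*dt.

    The closed-form I(S) is maximal at S = 1/r0_basic; delta_t is the t(S)
    quadrature there (I0 term retained, so the integrand stays regular at
    S0).  No-peak convention as in :func:`seirtime.sir.sir_peak_time`.
    """
    if params.r0_basic * params.s0 <= 1.0:
        return PeakSummary(delta_t=0.0, i_peak=params.i0, scaled_delta_t=0.0)
    s_peak = 1.0 / params.r0_basic
    dt = seir_time_of_s(s_peak, params, quad).value
    return PeakSummary(
        delta_t=dt,
        i_peak=seir_infectious_of_s(s_peak, params),
        scaled_delta_t=params.alpha * params.gamma * dt,
    )


def seir_growth_rate(params: EpidemicParameters) -> float:
    """Approximate growth rate Lambda = gamma*r0*(I0 + alpha*S0) - alpha*gamma.

    Reduces to gamma*(r0-1) in the SIR limit.  For S0 ~ 1, I0 << 1 this is
    ~ alpha*gamma*(r0-1): the epidemic grows 1/alpha times slower than an
    SIR epidemic with the same infectious period.
    """
    a = params.alpha
    return (
        params.gamma * params.r0_basic * (params.i0 + a * params.s0)
        - a * params.gamma
    )


def seir_r0_from_growth(
    lam: float, d_inf: float, d_inc: float, s0: float = 1.0, i0: float = 0.0
) -> float:
    """r0 from the approximate growth-rate relation.

    r0 = [1 + Lambda*(D' + D)] / [S0 + I0*(1 + D'/D)]; with S0 ~ 1 and
    I0 << 1 this is the exponential-generation-time result
    r0 ~ 1 + Lambda*(D + D').  D' = 0 recovers the SIR relation.
    """
    if not d_inf > 0:
        raise ParameterError(f"infectious period must be > 0, got {d_inf}")
    if d_inc < 0:
        raise ParameterError(f"incubation period must be >= 0, got {d_inc}")
    return (1.0 + lam * (d_inc + d_inf)) / (s0 + i0 * (1.0 + d_inc / d_inf))


def seir_r0_exact_from_growth(lam: float, d_inf: float, d_inc: float) -> float:
    """Exact relation r0 = (1 + Lambda*D')(1 + Lambda*D).

    Accounts for the generation-time distribution of the SEIR model (the
    convolution of two exponentials); the approximate relation lacks the
    Lambda^2*D'*D cross term and thus under-predicts r0.
    """
    if not d_inf > 0:
        raise ParameterError(f"infectious period must be > 0, got {d_inf}")
    if d_inc < 0:
        raise ParameterError(f"incubation period must be >= 0, got {d_inc}")
    return (1.0 + lam * d_inc) * (1.0 + lam * d_inf)


def seir_growth_rate_exact(r0_basic: float, d_inf: float, d_inc: float) -> float:
    """Dominant linearised growth rate: root of (1+L*D')(1+L*D) = r0.

    This is the positive eigenvalue of the linearised E-I subsystem with
    S ~ 1 (quadratic in Lambda; the larger root is returned).
    """
    if d_inc == 0:
        return (r0_basic - 1.0) / d_inf
    p = d_inc * d_inf
    q = d_inc + d_inf
    return (-q + math.sqrt(q * q + 4.0 * p * (r0_basic - 1.0))) / (2.0 * p)


def seir_early_time(t, params: EpidemicParameters):
    """Early-epidemic closed forms S(t), I(t) for the SEIR model.

    Same logarithm linearisation as the SIR case, with growth rate
    :func:`seir_growth_rate`; reduces to the SIR formulas at alpha = 1.
    """
    t = np.asarray(t, dtype=float)
    lam = seir_growth_rate(params)
    a = params.alpha
    r0, g, s0, i0 = params.r0_basic, params.gamma, params.s0, params.i0
    s = lam / (a * g * (r0 - 1.0 / s0) + (g * r0 * i0 / s0) * np.exp(lam * t))
    i = i0 + a * (s0 - 1.0 / r0) - (1.0 - 1.0 / (s0 * r0)) * a * s
    if t.ndim == 0:
        return float(s), float(i)
    return s, i


def seir_trajectory(
    params: EpidemicParameters,
    n_points: int = 400,
    i_stop: float | None = None,
    quad: QuadratureConfig | None = None,
) -> Trajectory:
    """Reconstruct the approximate SEIR trajectory on an S grid.

    Pairs t(S) from the quadrature with the closed-form E(S), I(S), R(S).
    """
    a = params.alpha
    s_grid = _sa.trajectory_s_grid(params, a, n_points, i_stop)
    times = np.array([seir_time_of_s(s, params, quad).value for s in s_grid])
    e_vals = np.asarray(seir_exposed_of_s(s_grid, params))
    i_vals = np.asarray(seir_infectious_of_s(s_grid, params))
    r_vals = np.asarray(seir_recovered_of_s(s_grid, params))
    return Trajectory(times=times, s=s_grid, e=e_vals, i=i_vals, r=r_vals)
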