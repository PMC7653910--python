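"""Exact semi-analytic solution of the SIR model.

Reducing the SIR system to a Bernoulli equation in 1/S' gives the
compartments in closed form as functions of the susceptible fraction,

    I(S) = S0 + I0 - S + (gamma/beta) * ln(S/S0),
    R(S) = (gamma/beta) * ln(S0/S),

and time as one numerical quadrature

    t - t0 = int_{S0}^{S} ds / ( s [ beta (s - S0 - I0) - gamma ln(s/S0) ] ),

which has no closed form.  The quadrature is the only numerical step, so the
solution is exact up to integration error: the reconstruction here matches a
high-accuracy ODE integration to ~1e-8 or better.

The infectious curve peaks where dI/dS = 0, i.e. at S = 1/r0_basic, so the
peak time is the quadrature evaluated there.  The dimensionless gamma*dt
depends only on r0_basic and I0.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy import integrate

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
    "sir_infectious_of_s",
    "sir_recovered_of_s",
    "sir_time_of_s",
    "sir_peak_time",
    "sir_early_time",
    "sir_growth_rate",
    "sir_r0_from_growth",
    "sir_final_size",
    "sir_trajectory",
    "peak_time_dimensionless",
]


def sir_infectious_of_s(S, params: EpidemicParameters):
    """Infectious fraction I at susceptible fraction S (exact closed form)."""
    return _sa.infectious_of_s(S, params, 1.0)


def sir_recovered_of_s(S, params: EpidemicParameters):
    """Recovered fraction R = (1/r0_basic) * ln(S0/S)."""
    return _sa.recovered_of_s(S, params)


def sir_time_of_s(
    S: float, params: EpidemicParameters, quad: QuadratureConfig | None = None
) -> QuadratureResult:
    """Days elapsed until the susceptible fraction has fallen to S."""
    return _sa.time_of_s(S, params, 1.0, quad)


def sir_peak_time(
    params: EpidemicParameters, quad: QuadratureConfig | None = None
) -> PeakSummary:
    """Peak timing of I from the exact quadrature evaluated at S = 1/r0.

    If ``r0_basic * s0 <= 1`` the infectious curve declines from the start;
    by convention this returns ``delta_t = 0`` with ``i_peak = i0`` so
    ensemble sweeps stay total.
    """
    if params.r0_basic * params.s0 <= 1.0:
        return PeakSummary(delta_t=0.0, i_peak=params.i0, scaled_delta_t=0.0)
    s_peak = 1.0 / params.r0_basic
    dt = sir_time_of_s(s_peak, params, quad).value
    return PeakSummary(
        delta_t=dt,
        i_peak=sir_infectious_of_s(s_peak, params),
        scaled_delta_t=params.gamma * dt,
    )


def sir_growth_rate(params: EpidemicParameters) -> float:
    """Early epidemic growth rate Lambda = gamma * (r0_basic - 1), per day."""
    return params.gamma * (params.r0_basic - 1.0)


def sir_r0_from_growth(lam: float, d_inf: float) -> float:
    """Basic reproduction number from growth rate: r0 = 1 + Lambda * D."""
    if not d_inf > 0:
        raise ParameterError(f"infectious period must be > 0, got {d_inf}")
    return 1.0 + lam * d_inf


def sir_early_time(t, params: EpidemicParameters):
    """Early-epidemic closed forms S(t), I(t) from the linearised quadrature.

    Expanding ln(S/S0) ~ S/S0 - 1 makes the t(S) integral elementary and
    yields logistic-type growth at rate Lambda = gamma*(r0-1).  Valid while
    I is well below its peak.
    """
    t = np.asarray(t, dtype=float)
    lam = sir_growth_rate(params)
    r0, g, s0, i0 = params.r0_basic, params.gamma, params.s0, params.i0
    s = lam / (g * (r0 - 1.0 / s0) + (g * r0 * i0 / s0) * np.exp(lam * t))
    i = 1.0 - 1.0 / r0 - (1.0 - 1.0 / (s0 * r0)) * s
    if t.ndim == 0:
        return float(s), float(i)
    return s, i


def sir_final_size(params: EpidemicParameters) -> float:
    """Ultimate susceptible fraction S_inf, root of I(S) = 0 below the peak."""
    return _sa.semianalytic_final_size(params, 1.0)


def sir_trajectory(
    params: EpidemicParameters,
    n_points: int = 400,
    i_stop: float | None = None,
    quad: QuadratureConfig | None = None,
) -> Trajectory:
    """Reconstruct the full exact trajectory on an S grid.

    Each grid point pairs t(S) from the quadrature with the closed-form
    I(S), R(S).  The grid runs from S0 down to where I has fallen to
    ``i_stop`` (default I0/10) past the peak.
    """
    s_grid = _sa.trajectory_s_grid(params, 1.0, n_points, i_stop)
    times = np.array([sir_time_of_s(s, params, quad).value for s in s_grid])
    i_vals = np.asarray(sir_infectious_of_s(s_grid, params))
    r_vals = np.asarray(sir_recovered_of_s(s_grid, params))
    return Trajectory(
        times=times, s=s_grid, e=np.zeros_like(s_grid), i=i_vals, r=r_vals
    )


def peak_time_dimensionless(
    r0_basic: float,
    i0: float,
    drop_i0: bool = False,
    quad: QuadratureConfig | None = None,
) -> float:
    """The dimensionless peak time gamma*dt as a function of (r0, I0) alone.

    With gamma factored out, the quadrature depends only on r0_basic and I0
    (taking E0 = 0 so S0 = 1 - I0).  ``drop_i0=True`` evaluates the variant
    with the I0 term deleted from the integrand; that integrand is
    log-divergent at s = S0, so the integration then starts at S0 - I0
    instead of S0 — a documented approximation, not the form used by
    :func:`sir_peak_time`.
    """
    params = EpidemicParameters(
        r0_basic=r0_basic, gamma=1.0, sigma=math.inf, i0=i0
    )
    if not drop_i0:
        return sir_peak_time(params, quad).scaled_delta_t

    quad = quad or QuadratureConfig()
    s0, r0 = params.s0, params.r0_basic

    def integrand(u: float) -> float:
        # d s = -s du cancels the 1/s factor; the denominator is negative on
        # the descending branch, hence the overall sign flip.
        s = s0 * math.exp(-u)
        return -1.0 / (r0 * (s - s0) - math.log(s / s0))

    u_lo = -math.log1p(-params.i0 / s0)  # u at s = S0 - I0
    u_hi = math.log(s0 * r0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        value, _err = integrate.quad(
            integrand, u_lo, u_hi, epsabs=quad.abs_tol, epsrel=quad.rel_tol,
            limit=quad.limit,
        )
    return float(value)
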