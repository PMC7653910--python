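"""Shared machinery for the semi-analytic SIR/SEIR solutions.

Both models reduce (exactly for SIR, approximately for SEIR under the
vanishing third derivative of R) to a Bernoulli equation in phi(S) = 1/S',
whose solution gives the compartments in closed form as functions of S and
time as a single quadrature

    t - t0 = int_{S0}^{S} ds / ( -s * beta * I_semi(s) ),

where I_semi(s) is the closed-form infectious fraction.  The integrand has a
boundary layer of width ~I0 at s = S0 (the denominator is beta*S0*I0 there),
so the integration variable is transformed to u = ln(S0/s), on which the
integrand is smooth and the layer sits at u = 0 where adaptive quadrature
refines naturally.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy import integrate, optimize

from .core import (
    DomainError,
    EpidemicParameters,
    QuadratureConfig,
    QuadratureError,
    QuadratureResult,
)

_DEFAULT_QUAD = QuadratureConfig()


def _check_s(S, s0: float) -> np.ndarray:
    arr = np.asarray(S, dtype=float)
    if np.any(arr <= 0) or np.any(arr > s0 * (1 + 1e-12)):
        raise DomainError(f"S must lie in (0, s0={s0}], got {S}")
    return np.minimum(arr, s0)


def infectious_of_s(S, params: EpidemicParameters, alpha_val: float):
    """Closed-form I(S) = I0 - alpha*(S - S0) + (alpha*gamma/beta)*ln(S/S0)."""
    s = _check_s(S, params.s0)
    g_over_b = params.gamma / params.beta  # = 1/r0_basic
    out = params.i0 - alpha_val * (s - params.s0) + alpha_val * g_over_b * np.log(
        s / params.s0
    )
    return out if out.ndim else float(out)


def exposed_of_s(S, params: EpidemicParameters, alpha_val: float):
    """Closed-form E(S) = 1 - I0 - alpha*S0 + (alpha-1)*[S - (gamma/beta) ln(S/S0)]."""
    s = _check_s(S, params.s0)
    g_over_b = params.gamma / params.beta
    out = (
        1.0
        - params.i0
        - alpha_val * params.s0
        + (alpha_val - 1.0) * (s - g_over_b * np.log(s / params.s0))
    )
    return out if out.ndim else float(out)


def recovered_of_s(S, params: EpidemicParameters):
    """R(S) = (gamma/beta) ln(S0/S); exact for both SIR and SEIR."""
    s = _check_s(S, params.s0)
    out = (params.gamma / params.beta) * np.log(params.s0 / s)
    return out if out.ndim else float(out)


def time_of_s(
    S: float,
    params: EpidemicParameters,
    alpha_val: float,
    quad: QuadratureConfig | None = None,
) -> QuadratureResult:
    """Evaluate the t(S) quadrature; strictly decreasing in S, 0 at S = S0."""
    quad = quad or _DEFAULT_QUAD
    s_target = float(_check_s(S, params.s0))
    u_max = math.log(params.s0 / s_target)
    if u_max == 0.0:
        return QuadratureResult(0.0, 0.0)

    beta = params.beta
    s0, i0 = params.s0, params.i0
    g_over_b = params.gamma / beta

    def integrand(u: float) -> float:
        s = s0 * math.exp(-u)
        i_semi = i0 - alpha_val * (s - s0) + alpha_val * g_over_b * math.log(s / s0)
        return 1.0 / (beta * i_semi)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        value, err, *rest = integrate.quad(
            integrand,
            0.0,
            u_max,
            epsabs=quad.abs_tol,
            epsrel=quad.rel_tol,
            limit=quad.limit,
            full_output=1,
        )
    if len(rest) > 1 or err > max(quad.abs_tol, quad.rel_tol * abs(value)) * 10:
        raise QuadratureError(
            f"t(S={s_target}) quadrature reached error estimate {err:.3e} "
            f"(requested abs {quad.abs_tol:.1e})",
            achieved=err,
        )
    return QuadratureResult(float(value), float(err))


def semianalytic_final_size(params: EpidemicParameters, alpha_val: float) -> float:
    """Root S_inf of the closed-form I(S) = 0 below the peak.

    For SIR (alpha = 1) this is the classic final-size relation
    r0*(S - S0 - I0) = ln(S/S0).
    """
    def f(s):
        return infectious_of_s(s, params, alpha_val)

    s_hi = min(1.0 / params.r0_basic, params.s0)
    if f(s_hi) <= 0:
        # no interior peak; epidemic declines from the start
        s_hi = params.s0
    lo = 1e-14
    return float(optimize.brentq(f, lo, s_hi, xtol=1e-15, rtol=1e-14))


def s_where_infectious_equals(
    params: EpidemicParameters, alpha_val: float, level: float
) -> float:
    """Smallest-S root of I_semi(S) = level on the declining branch."""
    s_peak = min(1.0 / params.r0_basic, params.s0)
    s_inf = semianalytic_final_size(params, alpha_val)

    def f(s):
        return infectious_of_s(s, params, alpha_val) - level

    if f(s_peak) <= 0:
        return s_peak
    return float(optimize.brentq(f, s_inf, s_peak, xtol=1e-15, rtol=1e-14))


def trajectory_s_grid(
    params: EpidemicParameters,
    alpha_val: float,
    n_points: int = 400,
    i_stop: float | None = None,
) -> np.ndarray:
    """Decreasing S grid from S0 down to where I_semi falls to ``i_stop``.

    Log-spaced in u = ln(S0/s) so the early exponential phase (u ~ I0) and
    the main wave are both resolved.  Default stop level is I0/10 past the
    peak, matching the ODE reference's stopping rule.
    """
    if i_stop is None:
        i_stop = params.i0 / 10.0
    s_end = s_where_infectious_equals(params, alpha_val, i_stop)
    u_end = math.log(params.s0 / s_end)
    u = np.concatenate(
        [[0.0], np.geomspace(max(params.i0 * 1e-2, 1e-12), u_end, n_points - 1)]
    )
    return params.s0 * np.exp(-u)
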