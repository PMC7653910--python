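"""High-accuracy numerical reference for the SIR and SEIR systems.

This module is the oracle the semi-analytic formulas are tested against.  It
integrates

    S' = -beta*I*S,  E' = beta*I*S - sigma*E,  I' = sigma*E - gamma*I,
    R' = gamma*I            (E absent and sigma*E -> beta*I*S for SIR)

with an explicit high-order Runge-Kutta scheme (DOP853) at tight tolerances
(default rel 1e-10, abs 1e-12); the systems are non-stiff at epidemic
scales.  Integration stops once the infectious fraction has fallen to a
tenth of its initial value after the peak, or at ``t_max``, whichever comes
first, so slow epidemics (long incubation stages) are never truncated
mid-wave.  The dense solution is sampled on a fixed step for reproducible
peak refinement and curve comparison across parameter draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .core import (
    EpidemicParameters,
    ParameterError,
    PeakSummary,
    PeakTruncationError,
    Trajectory,
)

__all__ = ["IntegratorConfig", "integrate_sir", "integrate_seir", "find_peak"]


@dataclass(frozen=True)
class IntegratorConfig:
    """Error control and sampling for the reference integrator."""

    rel_tol: float = 1e-10
    abs_tol: float = 1e-12
    t_max: float = 1000.0
    dense_output_step: float = 0.05
    #: stop once I has fallen to this fraction of I0 after its peak;
    #: None integrates all the way to t_max (e.g. for final-size checks)
    i_stop_fraction: float | None = 0.1

    def __post_init__(self):
        if not (0 < self.rel_tol <= 1e-3) or not (0 < self.abs_tol <= 1e-3):
            raise ParameterError("tolerances must lie in (0, 1e-3]")
        if not self.t_max > 0:
            raise ParameterError("t_max must be > 0")
        if not self.dense_output_step > 0:
            raise ParameterError("dense_output_step must be > 0")


_DEFAULT_CONFIG = IntegratorConfig()


def _integrate(params: EpidemicParameters, config: IntegratorConfig, sir: bool):
    beta, gamma, sigma = params.beta, params.gamma, params.sigma
    i_floor = (
        -1.0 if config.i_stop_fraction is None
        else params.i0 * config.i_stop_fraction
    )

    if sir:
        y0 = [params.s0, params.i0, 0.0]

        def rhs(t, y):
            s, i, r = y
            inf = beta * i * s
            return (-inf, inf - gamma * i, gamma * i)

        i_index = 1
    else:
        y0 = [params.s0, params.e0, params.i0, 0.0]

        def rhs(t, y):
            s, e, i, r = y
            inf = beta * i * s
            return (-inf, inf - sigma * e, sigma * e - gamma * i, gamma * i)

        i_index = 2

    def declined(t, y):
        return y[i_index] - i_floor

    declined.terminal = True
    declined.direction = -1

    sol = solve_ivp(
        rhs,
        (0.0, config.t_max),
        y0,
        method="DOP853",
        rtol=config.rel_tol,
        atol=config.abs_tol,
        dense_output=True,
        events=declined,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")

    t_end = sol.t[-1]
    n = max(2, int(math.floor(t_end / config.dense_output_step)) + 1)
    times = np.linspace(0.0, t_end, n)
    y = sol.sol(times)

    if sir:
        def dense(t):
            s_, i_, r_ = sol.sol(t)
            return s_, np.zeros_like(np.asarray(s_)), i_, r_
        s, i, r = y
        e = np.zeros_like(s)
    else:
        def dense(t):
            s_, e_, i_, r_ = sol.sol(t)
            return s_, e_, i_, r_
        s, e, i, r = y
    return Trajectory(times=times, s=s, e=e, i=i, r=r, dense=dense)


def integrate_sir(
    params: EpidemicParameters, config: IntegratorConfig | None = None
) -> Trajectory:
    """Reference SIR trajectory; requires the SIR sentinel (sigma = inf)."""
    if not params.is_sir:
        raise ParameterError("integrate_sir requires the SIR sentinel (sigma=inf)")
    return _integrate(params, config or _DEFAULT_CONFIG, sir=True)


def integrate_seir(
    params: EpidemicParameters, config: IntegratorConfig | None = None
) -> Trajectory:
    """Reference SEIR trajectory; requires finite sigma."""
    if params.is_sir:
        raise ParameterError("integrate_seir requires finite sigma")
    return _integrate(params, config or _DEFAULT_CONFIG, sir=False)


def find_peak(
    traj: Trajectory,
    compartment: str = "i",
    params: EpidemicParameters | None = None,
) -> PeakSummary:
    """Locate a compartment's maximum on a trajectory.

    The discrete argmax is refined with a three-point quadratic interpolant
    (exact for locally parabolic maxima).  If ``params`` is given the
    dimensionless ``alpha*gamma*delta_t`` is filled in, else it is NaN.

    Raises :class:`PeakTruncationError` if the maximum sits on the final
    sample while the curve is still rising — the run was too short.
    """
    values = traj.compartment(compartment)
    t = traj.times
    k = int(np.argmax(values))
    if k == len(values) - 1 and len(values) > 1 and values[-1] > values[0]:
        raise PeakTruncationError(
            f"{compartment} still rising at t={t[-1]:.3g}; increase t_max"
        )
    if k == 0:
        dt, v_peak = 0.0, float(values[0])
    elif traj.dense is not None:
        # continuous refinement on the integrator's dense output keeps the
        # located peak independent of the sampling step (and hence invariant
        # under common rescaling of all rates)
        from scipy.optimize import minimize_scalar

        idx = "seir".index(compartment.lower())
        res = minimize_scalar(
            lambda tau: -float(traj.dense(tau)[idx]),
            bounds=(t[k - 1], t[k + 1]),
            method="bounded",
            options={"xatol": 1e-10},
        )
        dt, v_peak = float(res.x), float(-res.fun)
    else:
        # quadratic through the three samples around the argmax
        t0, t1, t2 = t[k - 1], t[k], t[k + 1]
        v0, v1, v2 = values[k - 1], values[k], values[k + 1]
        denom = (t0 - t1) * (t0 - t2) * (t1 - t2)
        a = (t2 * (v1 - v0) + t1 * (v0 - v2) + t0 * (v2 - v1)) / denom
        b = (t2**2 * (v0 - v1) + t1**2 * (v2 - v0) + t0**2 * (v1 - v2)) / denom
        if a < 0:
            dt = -b / (2.0 * a)
            c = (
                t1 * t2 * (t1 - t2) * v0
                + t2 * t0 * (t2 - t0) * v1
                + t0 * t1 * (t0 - t1) * v2
            ) / denom
            v_peak = float(a * dt * dt + b * dt + c)
        else:  # flat triple; fall back to the sample
            dt, v_peak = float(t1), float(v1)
    scaled = math.nan
    if params is not None:
        scaled = params.alpha * params.gamma * dt
    return PeakSummary(delta_t=float(dt), i_peak=v_peak, scaled_delta_t=scaled)
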