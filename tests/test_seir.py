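"""The closed-form SEIR solution: reductions, conservation, and its
calibrated accuracy against the ODE reference (the R'''=0 approximation is
exactly what is being measured here, not numerics)."""

import numpy as np
import pytest

from seirtime import (
    DomainError,
    find_peak,
    integrate_seir,
    make_parameters,
    seir_early_time,
    seir_exposed_of_s,
    seir_growth_rate,
    seir_growth_rate_exact,
    seir_infectious_of_s,
    seir_peak_time_scaled,
    seir_r0_exact_from_growth,
    seir_r0_from_growth,
    seir_recovered_of_s,
    seir_time_of_s,
    seir_trajectory,
    sir_infectious_of_s,
    sir_peak_time,
    sir_recovered_of_s,
    sir_time_of_s,
)

# approximation tolerances calibrated at sigma,gamma in {1/2,1/5} and
# r0 in {2,7}, then frozen (worst observed: 0.073, 0.46, 0.46)
EI_OF_S_TOL = 0.10
PEAK_TIME_REL_TOL = 0.50
TIME_OF_S_REL_TOL = 0.50


def _s_grid(params, n=20):
    return np.linspace(1.0 / params.r0_basic, params.s0, n)


class TestClosedFormsOfS:
    def test_exposed_boundary_value(self):
        p = make_parameters(2.0, 0.5, 0.5, 1e-4, e0=0.01)
        assert seir_exposed_of_s(p.s0, p) == pytest.approx(p.e0, abs=1e-12)

    def test_exposed_vanishes_in_sir_limit(self):
        p = make_parameters(2.0, 0.5, None, 1e-4)
        grid = _s_grid(p)
        np.testing.assert_allclose(seir_exposed_of_s(grid, p), 0.0, atol=1e-15)

    def test_infectious_boundary_value(self, seir_params):
        assert seir_infectious_of_s(seir_params.s0, seir_params) == pytest.approx(
            seir_params.i0, abs=1e-15
        )

    def test_infectious_maximised_at_inverse_r0(self, seir_params):
        grid = np.linspace(0.35, seir_params.s0, 801)
        peak_val = seir_infectious_of_s(1.0 / seir_params.r0_basic, seir_params)
        assert peak_val >= np.max(seir_infectious_of_s(grid, seir_params))

    def test_domain_errors(self, seir_params):
        for op in (seir_exposed_of_s, seir_infectious_of_s, seir_recovered_of_s):
            with pytest.raises(DomainError):
                op(0.0, seir_params)
            with pytest.raises(DomainError):
                op(1.5, seir_params)

    def test_recovered_identical_to_sir(self, seir_params):
        grid = _s_grid(seir_params)
        np.testing.assert_array_equal(
            seir_recovered_of_s(grid, seir_params),
            sir_recovered_of_s(grid, seir_params),
        )

    def test_conservation_identity(self, seir_params):
        """S + E(S) + I(S) + R(S) = 1 holds algebraically on any grid."""
        grid = _s_grid(seir_params, 50)
        total = (
            grid
            + seir_exposed_of_s(grid, seir_params)
            + seir_infectious_of_s(grid, seir_params)
            + seir_recovered_of_s(grid, seir_params)
        )
        np.testing.assert_allclose(total, 1.0, atol=1e-12)

    def test_closed_forms_track_ode_at_matched_s(self, seir_params, seir_ode):
        semi = seir_trajectory(seir_params)
        e_ode = np.interp(-semi.s, -seir_ode.s, seir_ode.e)
        i_ode = np.interp(-semi.s, -seir_ode.s, seir_ode.i)
        assert np.max(np.abs(semi.e - e_ode)) < EI_OF_S_TOL
        assert np.max(np.abs(semi.i - i_ode)) < EI_OF_S_TOL


class TestAlphaOneReduction:
    """With the SIR sentinel every SEIR operation collapses onto its SIR
    counterpart (machine precision; same formulas with alpha = 1)."""

    def test_infectious(self, sir_params):
        grid = _s_grid(sir_params)
        np.testing.assert_allclose(
            seir_infectious_of_s(grid, sir_params),
            sir_infectious_of_s(grid, sir_params),
            rtol=0, atol=1e-14,
        )

    def test_time_quadrature(self, sir_params):
        assert seir_time_of_s(0.6, sir_params).value == pytest.approx(
            sir_time_of_s(0.6, sir_params).value, abs=1e-10
        )

    def test_peak_summary(self, sir_params):
        a = seir_peak_time_scaled(sir_params)
        b = sir_peak_time(sir_params)
        assert a == b


class TestTimeOfS:
    def test_zero_at_s0(self, seir_params):
        assert seir_time_of_s(seir_params.s0, seir_params).value == 0.0

    def test_relative_error_vs_ode_within_frozen_band(self, seir_params, seir_ode):
        for s in np.linspace(1.0 / seir_params.r0_basic, 0.99 * seir_params.s0, 8):
            t_semi = seir_time_of_s(float(s), seir_params).value
            t_ode = np.interp(-s, -seir_ode.s, seir_ode.times)
            assert abs(t_semi - t_ode) / t_ode < TIME_OF_S_REL_TOL


class TestPeakTimeScaled:
    def test_pure_time_rescaling_leaves_scaled_value(self):
        a = seir_peak_time_scaled(make_parameters(2.0, 0.5, 0.5, 1e-4))
        b = seir_peak_time_scaled(make_parameters(2.0, 0.2, 0.2, 1e-4))
        assert a.scaled_delta_t == pytest.approx(b.scaled_delta_t, abs=1e-9)

    def test_against_ode_argmax_within_frozen_band(self):
        p = make_parameters(2.0, 0.25, 1.0 / 3.0, 1e-4)
        ode_peak = find_peak(integrate_seir(p), "i", p)
        semi = seir_peak_time_scaled(p)
        assert semi.delta_t == pytest.approx(
            ode_peak.delta_t, rel=PEAK_TIME_REL_TOL
        )

    def test_no_peak_convention(self):
        summary = seir_peak_time_scaled(make_parameters(0.8, 0.5, 0.5, 1e-4))
        assert summary.delta_t == 0.0 and summary.scaled_delta_t == 0.0


class TestEarlyTime:
    def test_reduces_to_sir_formulas(self, sir_params):
        from seirtime import sir_early_time

        t = np.linspace(0.0, 20.0, 7)
        s_seir, i_seir = seir_early_time(t, sir_params)
        s_sir, i_sir = sir_early_time(t, sir_params)
        np.testing.assert_allclose(s_seir, s_sir, rtol=1e-14)
        np.testing.assert_allclose(i_seir, i_sir, rtol=1e-12)

    def test_initial_conditions_reproduced(self, seir_params):
        # with e0 = 0 the closed form returns (S0, I0) at t0 identically
        s, i = seir_early_time(0.0, seir_params)
        assert s == pytest.approx(seir_params.s0, abs=1e-14)
        assert i == pytest.approx(seir_params.i0, abs=1e-14)

    def test_fitted_ode_slope_closer_to_exact_than_approximate_rate(self):
        """The exact growth relation beats the series-expansion one."""
        p = make_parameters(2.0, 0.5, 0.5, 1e-6)
        traj = integrate_seir(p)
        pre_peak = np.arange(len(traj.i)) <= np.argmax(traj.i)
        mask = pre_peak & (traj.i > 10 * p.i0) & (traj.i < 1e3 * p.i0)
        fit = np.polyfit(traj.times[mask], np.log(traj.i[mask]), 1)[0]
        lam_exact = seir_growth_rate_exact(p.r0_basic, p.d_inf, p.d_inc)
        lam_approx = seir_growth_rate(p)
        assert abs(fit - lam_exact) < abs(fit - lam_approx)


class TestGrowthRateRelations:
    def test_sir_reduction(self, sir_params):
        assert seir_growth_rate(sir_params) == pytest.approx(
            sir_params.gamma * (sir_params.r0_basic - 1.0), rel=1e-14
        )

    def test_arithmetic_value(self):
        # sigma = gamma = 0.5 (alpha = 1/2), r0 = 2, S0 ~ 1, I0 ~ 0
        p = make_parameters(2.0, 0.5, 0.5, 1e-12)
        assert seir_growth_rate(p) == pytest.approx(0.25, abs=1e-9)

    def test_small_seed_limit(self):
        p = make_parameters(3.0, 0.5, 0.25, 1e-8)
        expected = p.alpha * p.gamma * (p.r0_basic - 1.0)
        assert seir_growth_rate(p) == pytest.approx(expected, rel=1e-6)

    def test_r0_from_growth_reductions(self):
        assert seir_r0_from_growth(0.5, 2.0, 0.0) == pytest.approx(2.0)
        assert seir_r0_from_growth(0.25, 2.0, 2.0) == pytest.approx(2.0)

    def test_r0_round_trip(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            r0 = rng.uniform(1.2, 7.0)
            d_inf, d_inc = rng.uniform(2.0, 5.0, 2)
            i0 = 10.0 ** rng.uniform(-6, -2)
            p = make_parameters(r0, 1.0 / d_inf, 1.0 / d_inc, i0)
            back = seir_r0_from_growth(
                seir_growth_rate(p), d_inf, d_inc, p.s0, p.i0
            )
            assert back == pytest.approx(r0, rel=1e-12)

    def test_exact_relation_values(self):
        assert seir_r0_exact_from_growth(0.25, 2.0, 2.0) == pytest.approx(2.25)
        assert seir_r0_exact_from_growth(0.3, 2.0, 0.0) == pytest.approx(1.6)

    def test_exact_exceeds_approximate_by_cross_term(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            lam = rng.uniform(0.05, 0.6)
            d_inf, d_inc = rng.uniform(2.0, 5.0, 2)
            exact = seir_r0_exact_from_growth(lam, d_inf, d_inc)
            approx = seir_r0_from_growth(lam, d_inf, d_inc, s0=1.0, i0=0.0)
            assert exact - approx == pytest.approx(lam**2 * d_inc * d_inf, rel=1e-12)

    def test_exact_rate_inverts_exact_relation(self):
        lam = seir_growth_rate_exact(2.0, 4.0, 3.0)
        assert seir_r0_exact_from_growth(lam, 4.0, 3.0) == pytest.approx(2.0, rel=1e-12)


class TestApproximationQuality:
    def test_error_grows_as_exposed_stage_lengthens(self):
        """sup|I_semi(t) - I_ode(t)| is larger at alpha=0.5 than alpha=0.9."""
        sups = {}
        for sigma, label in ((0.5, 0.5), (4.5, 0.9)):
            p = make_parameters(2.0, 0.5, sigma, 1e-4)
            ode = integrate_seir(p)
            semi = seir_trajectory(p, n_points=200)
            t = np.clip(semi.times, 0.0, ode.times[-1])
            sups[label] = np.max(np.abs(semi.i - ode.dense(t)[2]))
        assert sups[0.5] > sups[0.9]
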