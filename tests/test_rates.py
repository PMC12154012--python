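import math

import numpy as np
import pytest
from scipy.integrate import quad

from inactikin.models_primary import WeibullModel
from inactikin.profiles import constant_profile, linear_ramp, ramp_sine_profile
from inactikin.rates import (
    ExponentialRampFactor,
    HistoryStateWeibullRate,
    build_weibull_rate,
    history_increment,
    path_independent_rate,
    table1_rate,
)
from inactikin.solver import SolverSettings, solve_rk4


class TestPathIndependentRate:
    def test_first_order_rate_is_state_free(self):
        m = WeibullModel(b=1.7, n=1.0)
        for y in (0.0, -0.5, -3.0):
            assert path_independent_rate(m, y) == pytest.approx(-1.7)

    def test_state_form_value(self):
        # substitute log10S=-1, b=1, n=0.5: -0.5 * 1^2 * 1^(-1) = -0.5,
        # and independently via f'(f^-1(-1))
        m = WeibullModel(b=1.0, n=0.5)
        r = path_independent_rate(m, -1.0)
        assert r == pytest.approx(-0.5)
        t_star = m.inverse_time(-1.0)
        assert r == pytest.approx(float(m.deriv(t_star)), rel=1e-12)

    def test_no_lethality_when_b_zero(self):
        m = WeibullModel(b=0.0, n=0.545)
        assert path_independent_rate(m, -2.0) == 0.0

    def test_positive_log10S_clamped_with_warning(self):
        m = WeibullModel(b=1.0, n=1.0)
        with pytest.warns(UserWarning):
            assert path_independent_rate(m, 0.05) == pytest.approx(-1.0)

    def test_depends_only_on_momentary_state(self, salmonella_family):
        """Two different paths ending at the same [log10S, T] give the
        same momentary rate — the defining property."""
        rate = build_weibull_rate(salmonella_family, "path_independent")
        y = -1.5
        prof_a = constant_profile(72.0, 10.0)
        prof_b = linear_ramp(52.0, 10.0, 2.0)  # reaches 72 degC at t=2
        ra, _ = rate.rhs(4.0, y, (), prof_a)
        rb, _ = rate.rhs(2.0, y, (), prof_b)
        assert ra == pytest.approx(rb, rel=1e-12)


class TestHistoryIntegral:
    def test_unweighted_increment_is_b(self):
        assert history_increment(2.0, 0.0, 1.3) == pytest.approx(1.3)

    def test_negative_weight_singular_at_zero(self):
        assert history_increment(0.0, -0.5, 1.0) == math.inf

    def test_constant_temperature_average_recovers_b(self, salmonella_family):
        # at constant T: I_m = b t^(m+1)/(m+1) so Bbar = b for every m
        b = salmonella_family.b(np.array([72.0]))
        for m in (-0.5, 0.0, 1.0, 2.0):
            rate = HistoryStateWeibullRate(salmonella_family, m=m)
            t = 1.7
            I = b * t ** (m + 1.0) / (m + 1.0)
            assert rate._bbar(t, I, np.array([72.0])) == pytest.approx(b, rel=1e-12)

    def test_ode_carried_integral_matches_quadrature(self, salmonella_family):
        """The auxiliary state carried by RK4 equals adaptive quadrature
        of t^m b(T(t)) under the dynamic test profile."""
        prof = ramp_sine_profile(1.0)
        m = 1.0
        rate = build_weibull_rate(salmonella_family, "history_state", m=m)
        settings = SolverSettings(dt=1e-3, t_end=0.5)

        # carry the aux state manually through the solver loop
        y, aux = 0.0, (0.0,)
        t0 = 0.0
        for i in range(1, 501):
            t1 = i * 1e-3
            if i <= rate.startup_steps or rate.needs_analytic_step(t0, y):
                y, aux = rate.analytic_step(t0, t1, y, aux, prof)
            else:
                h = t1 - t0
                k1, a1 = rate.rhs(t0, y, aux, prof)
                k2, a2 = rate.rhs(t0 + h / 2, y + h / 2 * k1, (aux[0] + h / 2 * a1[0],), prof)
                k3, a3 = rate.rhs(t0 + h / 2, y + h / 2 * k2, (aux[0] + h / 2 * a2[0],), prof)
                k4, a4 = rate.rhs(t1, y + h * k3, (aux[0] + h * a3[0],), prof)
                y += h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
                aux = (aux[0] + h / 6 * (a1[0] + 2 * a2[0] + 2 * a3[0] + a4[0]),)
            t0 = t1
        I_quad, _ = quad(lambda tau: tau**m * salmonella_family.b(prof.conditions(tau)),
                         0.0, 0.5, limit=200)
        assert aux[0] == pytest.approx(I_quad, abs=1e-6)

    def test_average_tends_to_initial_b_at_zero(self, salmonella_family):
        """Bbar(t) -> b(T(0)) as t -> 0+ for all m > -1 (the analytic limit
        used by the solver at the start of every run)."""
        prof = linear_ramp(70.0, 10.0, 1.0)
        b0 = salmonella_family.b(prof.conditions(0.0))
        for m in (-0.5, 0.0, 1.0, 2.0):
            rate = HistoryStateWeibullRate(salmonella_family, m=m)
            for t in (1e-3, 1e-4, 1e-5):
                I, _ = quad(lambda tau: tau**m * salmonella_family.b(prof.conditions(tau)),
                            0.0, t, limit=200)
                bbar = rate._bbar(t, I, prof.conditions(t))
                assert bbar == pytest.approx(b0, rel=5e-3 if t > 1e-4 else 5e-4)

    def test_weight_must_exceed_minus_one(self, salmonella_family):
        with pytest.raises(ValueError):
            HistoryStateWeibullRate(salmonella_family, m=-1.0)


class TestDirectRates:
    def test_koseki_rate_vanishes_at_floor(self):
        params = dict(kmax=2.0, Nmin=100.0, mK=0.7, N0=1e8)
        assert table1_rate("koseki", params, N=100.0) == 0.0

    def test_chick_rate(self):
        assert table1_rate("chick", {"kL": 1.0}, N=100.0) == pytest.approx(-100.0)

    def test_zhu_chen_initial_rate_without_lag(self):
        params = dict(kmax=3.0, C_over_C0=0.0, Nres=100.0, N0=1e8)
        assert table1_rate("zhu_chen", params, N=1e8, t=0.0) == pytest.approx(
            -3.0 * (1e8 - 100.0)
        )

    def test_zhu_chen_rate_vanishes_at_residual(self):
        params = dict(kmax=3.0, C_over_C0=2.0, Nres=100.0, N0=1e8)
        assert table1_rate("zhu_chen", params, N=100.0, t=1.0) == 0.0


class TestVariantsDivergeUnderDynamicProfile:
    def test_state_and_history_rates_differ_mid_run(self, salmonella_family):
        """Under the dynamic test profile the path-independent and the
        m=1 history-state rates give different survival at t=1 min."""
        prof = ramp_sine_profile(1.0)
        settings = SolverSettings(dt=1e-3, t_end=1.0)
        pi = solve_rk4(build_weibull_rate(salmonella_family, "path_independent"),
                       prof, settings)
        hs = solve_rk4(build_weibull_rate(salmonella_family, "history_state", m=1.0),
                       prof, settings)
        assert abs(pi.log10S[-1] - hs.log10S[-1]) > 0.05


class TestExponentialRampFactor:
    def test_factor_is_one_at_constant_temperature(self, salmonella_family):
        prof = constant_profile(72.0, 2.0)
        settings = SolverSettings(dt=1e-3, t_end=2.0)
        base = build_weibull_rate(salmonella_family, "derivative")
        wrapped = build_weibull_rate(salmonella_family, "derivative",
                                     exp_multiplier_a=0.3)
        assert isinstance(wrapped, ExponentialRampFactor)
        c0 = solve_rk4(base, prof, settings)
        c1 = solve_rk4(wrapped, prof, settings)
        np.testing.assert_allclose(c1.log10S, c0.log10S, atol=1e-12)

    def test_factor_scales_rate_on_a_ramp(self, salmonella_family):
        prof = linear_ramp(70.0, 2.0, 1.0)
        base = build_weibull_rate(salmonella_family, "derivative")
        wrapped = ExponentialRampFactor(base, a=0.3)
        r0, _ = base.rhs(0.5, -1.0, (), prof)
        r1, _ = wrapped.rhs(0.5, -1.0, (), prof)
        assert r1 == pytest.approx(r0 * math.exp(0.3 * 2.0), rel=1e-12)
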