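import math

import numpy as np
import pandas as pd
import pytest

from inactikin.curves import SurvivalCurve
from inactikin.fitting_eval import (
    compare_rate_variants,
    fit_primary_isothermal,
    fit_secondary,
    refine_dynamic,
    rmse,
)
from inactikin.profiles import linear_ramp
from inactikin.rates import WeibullFamily
from inactikin.solver import SolverSettings, solve_recursive
from inactikin.synthetic_data import case_study_rmse_table, generate_isothermal_dataset


def _curve(times, values, **kw):
    return SurvivalCurve(np.asarray(times, float), np.asarray(values, float), **kw)


class TestRMSE:
    def test_identical_curves_give_zero(self):
        c = _curve([1, 2, 3], [-1, -2, -3])
        assert rmse(c, c) == 0.0

    def test_dof_denominator(self):
        measured = _curve([1, 2], [-1.0 + 0.1, -2.0 - 0.1])
        calc = _curve([0, 1, 2], [0.0, -1.0, -2.0])
        assert rmse(measured, calc, p=0) == pytest.approx(0.1)
        assert rmse(measured, calc, p=1) == pytest.approx(math.sqrt(0.02), rel=1e-12)

    def test_too_few_points_raises(self):
        measured = _curve([1.0], [-1.0])
        calc = _curve([0, 2], [0.0, -2.0])
        with pytest.raises(ValueError):
            rmse(measured, calc, p=1)

    def test_interpolates_calculated_to_measured_times(self):
        measured = _curve([0.5, 1.5], [-0.5, -1.5])
        calc = _curve([0, 1, 2], [0.0, -1.0, -2.0])  # linear: interpolation exact
        assert rmse(measured, calc) == pytest.approx(0.0, abs=1e-15)

    def test_scales_linearly_with_residuals(self):
        calc = _curve([0, 1, 2], [0.0, -1.0, -2.0])
        m1 = _curve([1, 2], [-1.1, -2.1])
        m2 = _curve([1, 2], [-1.2, -2.2])
        assert rmse(m2, calc) == pytest.approx(2.0 * rmse(m1, calc), rel=1e-12)


class TestPrimaryIsothermalFit:
    def test_noiseless_exact_recovery(self):
        delta, n = 1.36, 1.25
        curves = {}
        for T, d in [(115.0, 6.8), (120.0, delta), (125.0, 0.27)]:
            t = np.linspace(0.2, 5.0, 10) * d
            curves[T] = _curve(t, -((t / d) ** n))
        fit = fit_primary_isothermal(curves, share_n=True)
        assert fit.estimates["n"] == pytest.approx(n, abs=1e-6)
        assert fit.estimates["delta"][120.0] == pytest.approx(delta, rel=1e-6)
        assert fit.rmse == pytest.approx(0.0, abs=1e-8)

    def test_noisy_recovery_within_five_percent_median(self):
        """Monte-Carlo: with 0.1 log10 noise and 10 points per curve the
        median relative delta error stays below 5%."""
        errs = []
        for rep in range(50):
            data = generate_isothermal_dataset(
                (115.0, 120.0, 125.0, 130.0), delta_ref=1.36, Tref=120.0,
                z=7.2, n=1.25, points_per_curve=10, noise_sd=0.1, seed=500 + rep)
            fit = fit_primary_isothermal(data, share_n=True)
            d_hat = fit.estimates["delta"][120.0]
            errs.append(abs(d_hat - 1.36) / 1.36)
        assert float(np.median(errs)) < 0.05

    def test_single_point_curve_rejected(self):
        with pytest.raises(ValueError):
            fit_primary_isothermal({60.0: _curve([1.0], [-1.0])})

    def test_independent_n_per_curve(self):
        curves = {}
        for T, d, n in [(115.0, 6.8, 1.1), (125.0, 0.27, 1.4)]:
            t = np.linspace(0.2, 5.0, 12) * d
            curves[T] = _curve(t, -((t / d) ** n))
        fit = fit_primary_isothermal(curves, share_n=False)
        assert fit.estimates["n"][115.0] == pytest.approx(1.1, abs=1e-5)
        assert fit.estimates["n"][125.0] == pytest.approx(1.4, abs=1e-5)


class TestSecondaryFit:
    def test_two_point_bigelow_closed_form(self):
        # one decade over 7.2 degC: z = 7.2 exactly
        fit = fit_secondary([(110.0, 1.36), (117.2, 0.136)], "bigelow", Tref=110.0)
        assert fit.estimates["z"] == pytest.approx(7.2, rel=1e-9)
        assert fit.estimates["delta_ref"] == pytest.approx(1.36, rel=1e-9)

    def test_noiseless_log_logistic_recovery(self):
        T = np.linspace(60.0, 80.0, 9)
        b = np.log1p(np.exp(0.348 * (T - 66.34)))
        fit = fit_secondary(list(zip(T, b)), "log_logistic")
        assert fit.estimates["k"] == pytest.approx(0.348, rel=1e-6)
        assert fit.estimates["Tc"] == pytest.approx(66.34, rel=1e-6)

    def test_bigelow_requires_tref(self):
        with pytest.raises(ValueError):
            fit_secondary([(110.0, 1.36), (117.2, 0.136)], "bigelow")

    def test_increasing_delta_rejected(self):
        # delta growing with T would mean a negative z
        with pytest.raises(ValueError):
            fit_secondary([(110.0, 0.1), (120.0, 1.0)], "bigelow", Tref=110.0)

    def test_degenerate_temperatures_rejected(self):
        with pytest.raises(ValueError):
            fit_secondary([(110.0, 1.0), (110.0, 0.9)], "bigelow", Tref=110.0)


class TestDynamicRefinement:
    @pytest.fixture()
    def dynamic_data(self, bsporo_family):
        curves = []
        for HR in (1.0, 10.0):
            t_end = 20.0 / HR + 4.0  # ramp 110->130 then continue? keep inside
            prof = linear_ramp(110.0, HR, 20.0 / HR)
            sol = solve_recursive(bsporo_family, prof,
                                  SolverSettings(dt=1e-3, t_end=prof.t_end))
            times = np.linspace(prof.t_end / 8, prof.t_end, 8)
            curves.append(SurvivalCurve(times, sol.interpolate(times), condition=prof))
        return curves

    def test_recovers_generating_parameters(self, dynamic_data):
        start = {"delta_ref": 1.8, "z": 6.0, "n": 1.1}  # perturbed start
        fit = refine_dynamic(dynamic_data, start, Tref=120.0,
                             variant="path_independent", dt=1e-2)
        assert fit.estimates["z"] == pytest.approx(7.2, rel=0.02)
        assert fit.estimates["n"] == pytest.approx(1.25, rel=0.02)
        assert fit.estimates["delta_ref"] == pytest.approx(1.36, rel=0.02)

    def test_refinement_does_not_increase_sse(self, dynamic_data, bsporo_family):
        start = {"delta_ref": 1.8, "z": 6.0, "n": 1.1}

        def sse(params):
            fam = WeibullFamily.from_bigelow(params["delta_ref"], 120.0,
                                             params["z"], params["n"])
            total = 0.0
            for c in dynamic_data:
                sol = solve_recursive(fam, c.condition,
                                      SolverSettings(dt=1e-2, t_end=c.condition.t_end))
                total += float(np.sum((sol.interpolate(c.times) - c.log10S) ** 2))
            return total

        fit = refine_dynamic(dynamic_data, start, Tref=120.0, dt=1e-2)
        assert fit.extra["sse"] <= sse(start) + 1e-12

    def test_mismatched_variant_fits_worse(self, dynamic_data):
        """Refitting the derivative (path-dependent) rate to data generated
        by the path-independent rate leaves systematic residuals."""
        start = {"delta_ref": 1.36, "z": 7.2, "n": 1.25}
        matched = refine_dynamic(dynamic_data, start, Tref=120.0,
                                 variant="path_independent", dt=1e-2)
        mismatched = refine_dynamic(dynamic_data, start, Tref=120.0,
                                    variant="derivative", dt=1e-2)
        assert matched.rmse < mismatched.rmse

    def test_requires_profiles(self):
        c = _curve([1.0, 2.0], [-1.0, -2.0])
        with pytest.raises(ValueError):
            refine_dynamic([c], {"delta_ref": 1.0, "z": 7.0, "n": 1.0}, Tref=120.0)


class TestVariantComparison:
    def test_packaged_case_table_headline_count(self):
        """On the 16 published dynamic conditions the path-independent
        rate beats the derivative rate 14 times."""
        df = case_study_rmse_table()
        assert len(df) == 16
        wins = compare_rate_variants(df, "rmse_path_independent", "rmse_derivative")
        assert wins == 14

    def test_ties_count_for_neither(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [1.0, 2.0]})
        assert compare_rate_variants(df) == 0

    def test_single_pair(self):
        assert compare_rate_variants(pd.DataFrame({"a": [0.389], "b": [7.56]})) == 1

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            compare_rate_variants(pd.DataFrame())
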