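"""Gestational physiology curves: evaluation, vertex analytics, fitting."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import gestag as g
from gestag.errors import (
    DegenerateCurveError,
    PhysioRangeError,
    UnderdeterminedError,
    ZeroVarianceError,
)


class TestEvalGFR:
    @pytest.mark.parametrize(
        "curve, week, expected",
        [
            (g.GFRQuadratic(), 0.0, 99.04),
            (g.GFRQuadratic(a2=0, a1=0, a0=100.0), 17.3, 100.0),
            (
                g.GFRQuadratic(),
                27.08,
                -0.077 * 27.08**2 + 4.17 * 27.08 + 99.04,  # ~155.5
            ),
        ],
    )
    def test_values(self, curve, week, expected):
        assert g.eval_gfr(curve, week) == pytest.approx(expected, rel=1e-12)

    def test_default_midpregnancy_value_near_155(self):
        assert g.eval_gfr(g.GFRQuadratic(), 27.08) == pytest.approx(155.5, abs=0.1)

    def test_nonpositive_result_errors(self):
        with pytest.raises(DegenerateCurveError):
            g.eval_gfr(g.GFRQuadratic(a2=-10.0, a1=0.0, a0=10.0), 40.0)


class TestGFRPeak:
    def test_published_vertex_and_fold(self):
        week, fold = g.gfr_peak(g.GFRQuadratic())
        assert round(week, 1) == 27.1
        assert round(fold, 2) == 1.57

    def test_vertex_formula(self):
        week, _ = g.gfr_peak(g.GFRQuadratic(a2=-1.0, a1=10.0, a0=25.0))
        assert week == pytest.approx(5.0)

    def test_convex_curve_has_no_interior_maximum(self):
        with pytest.raises(DegenerateCurveError):
            g.gfr_peak(g.GFRQuadratic(a2=0.1, a1=1.0, a0=100.0))

    @given(
        a2=st.floats(-0.5, -0.01),
        a1=st.floats(1.0, 6.0),
        a0=st.floats(50.0, 150.0),
    )
    def test_vertex_dominates_dense_grid(self, a2, a1, a0):
        curve = g.GFRQuadratic(a2=a2, a1=a1, a0=a0)
        week, _ = g.gfr_peak(curve)
        grid = np.linspace(0, 42, 400)
        try:
            values = g.eval_gfr(curve, grid)
        except DegenerateCurveError:
            return  # curve dips below zero in range: nothing to compare
        peak_val = a2 * week**2 + a1 * week + a0
        assert peak_val >= values.max() - 1e-9


class TestPlasmaVolume:
    def test_centering_week_is_sign_independent(self):
        for sign in (1, -1):
            c = g.PlasmaVolumeSigmoid(sign=sign)
            assert g.eval_plasma_volume(c, 9.2) == pytest.approx(
                2378 + 796.2 / (0.62 + 4.4), rel=1e-12
            )

    def test_zero_numerator_gives_offset(self):
        c = g.PlasmaVolumeSigmoid(num=0.0)
        assert g.eval_plasma_volume(c, 30.0) == pytest.approx(2378.0)

    def test_printed_sign_large_week_limit_is_offset(self):
        c = g.PlasmaVolumeSigmoid()
        assert g.eval_plasma_volume(c, 42.0) == pytest.approx(2378.0, abs=2.0)


class TestFractionalPlasmaMass:
    @pytest.mark.parametrize(
        "dp, dt, expected", [(0.5, 2.0, 0.25), (1.3, 1.3, 1.0)]
    )
    def test_ratio(self, dp, dt, expected):
        assert g.compute_fpm(dp, dt) == expected

    def test_zero_total_gain_is_undefined(self):
        with pytest.raises(PhysioRangeError):
            g.compute_fpm(0.3, 0.0)

    @pytest.mark.parametrize(
        "line, week, expected",
        [
            (g.FractionalPlasmaLine(), 0.0, 0.32),
            (g.FractionalPlasmaLine(), 20.0, 0.20),
            (g.FractionalPlasmaLine(slope=0.0, intercept=0.3), 33.0, 0.3),
        ],
    )
    def test_line_values(self, line, week, expected):
        assert g.eval_fpm(line, week) == pytest.approx(expected, rel=1e-12)

    def test_out_of_physiological_range_errors(self):
        with pytest.raises(PhysioRangeError):
            g.eval_fpm(g.FractionalPlasmaLine(slope=-0.01, intercept=0.32), 40.0)
        with pytest.raises(PhysioRangeError):
            g.eval_fpm(g.FractionalPlasmaLine(slope=0.1, intercept=0.9), 10.0)


class TestRSquared:
    def test_perfect_prediction(self):
        assert g.r_squared([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_mean_prediction_scores_zero(self):
        obs = [1.0, 2.0, 3.0]
        assert g.r_squared(obs, [2.0, 2.0, 2.0]) == pytest.approx(0.0)

    def test_hand_value(self):
        assert g.r_squared([1.0, 2.0, 3.0], [1.0, 2.0, 4.0]) == pytest.approx(0.5)

    def test_constant_observations_undefined(self):
        with pytest.raises(ZeroVarianceError):
            g.r_squared([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestFitGFR:
    def test_noise_free_recovery(self, gfr_noise_free):
        truth = g.GFRQuadratic()
        fit, r2 = g.fit_gfr_quadratic(gfr_noise_free)
        assert fit.a2 == pytest.approx(truth.a2, rel=1e-8)
        assert fit.a1 == pytest.approx(truth.a1, rel=1e-8)
        assert fit.a0 == pytest.approx(truth.a0, rel=1e-8)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_constant_data_fits_constant(self):
        rows = [("s1", "normal", w, "gfr", 100.0) for w in (0.0, 10.0, 20.0, 30.0)]
        fit, r2 = g.fit_gfr_quadratic(g.LongitudinalSeries.from_records(rows))
        assert abs(fit.a2) < 1e-10 and abs(fit.a1) < 1e-8
        assert fit.a0 == pytest.approx(100.0)
        assert r2 == 1.0

    def test_underdetermined(self):
        rows = [("s1", "normal", w, "gfr", 100.0 + w) for w in (0.0, 10.0)]
        with pytest.raises(UnderdeterminedError):
            g.fit_gfr_quadratic(g.LongitudinalSeries.from_records(rows))

    def test_noisy_cohort_estimates_within_sampling_error(self):
        """Monte-Carlo over seeds: coefficients near truth, r2 < 1."""
        truth = g.GFRQuadratic()
        fits = []
        for seed in range(20):
            cohort = g.generate(g.default_cohort("gfr", seed=seed))
            fit, r2 = g.fit_gfr_quadratic(cohort)
            assert r2 < 1.0
            fits.append([fit.a2, fit.a1, fit.a0])
        mean = np.mean(fits, axis=0)
        # average fit over 20 cohorts of n=25: comfortably near truth
        assert mean[2] == pytest.approx(truth.a0, abs=3 * 21.2 / np.sqrt(25 * 20))
        grid = np.array([0.0, 16.0, 26.0, 36.0])
        truth_vals = g.eval_gfr(truth, grid)
        mean_vals = mean[0] * grid**2 + mean[1] * grid + mean[2]
        assert np.all(np.abs(mean_vals - truth_vals) < 3 * 21.2 / np.sqrt(25 * 20))


class TestFitPlasmaVolume:
    def test_noise_free_recovery_from_default_init(self):
        truth = g.PlasmaVolumeSigmoid()
        weeks = (0.0, 8.0, 14.0, 20.0, 26.0, 32.0, 38.0)
        rows = [
            ("s1", "normal", w, "plasma_volume", g.eval_plasma_volume(truth, w))
            for w in weeks
        ]
        fit, r2 = g.fit_plasma_volume_sigmoid(g.LongitudinalSeries.from_records(rows))
        for name in ("num", "d0", "d1", "rate", "t_mid", "offset"):
            assert getattr(fit, name) == pytest.approx(
                getattr(truth, name), rel=1e-4
            )
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_too_few_weeks(self):
        rows = [
            ("s1", "normal", w, "plasma_volume", 2500.0 + w)
            for w in (0.0, 10.0, 20.0, 30.0, 40.0)
        ]
        with pytest.raises(UnderdeterminedError):
            g.fit_plasma_volume_sigmoid(g.LongitudinalSeries.from_records(rows))

    def test_noisy_cohort_fitted_curve_within_one_sd(self):
        truth = g.PlasmaVolumeSigmoid()
        spec = g.default_cohort("plasma_volume", seed=3)
        fit, _ = g.fit_plasma_volume_sigmoid(g.generate(spec))
        weeks = np.array(spec.weeks)
        assert np.all(
            np.abs(
                g.eval_plasma_volume(fit, weeks) - g.eval_plasma_volume(truth, weeks)
            )
            < 52.3
        )


class TestFitFPMLine:
    @staticmethod
    def _series(weeks, line, rate=0.3125, include_week0=False):
        rows = []
        for w in weeks:
            total = rate * w
            frac = line.slope * w + line.intercept
            rows.append(("s1", "normal", w, "total_mass_gain", total))
            rows.append(("s1", "normal", w, "plasma_mass_gain", frac * total))
        if include_week0:
            rows.append(("s1", "normal", 0.0, "total_mass_gain", 0.0))
            rows.append(("s1", "normal", 0.0, "plasma_mass_gain", 0.0))
        return g.LongitudinalSeries.from_records(rows)

    def test_noise_free_recovery(self):
        truth = g.FractionalPlasmaLine()
        fit, r2 = g.fit_fpm_line(self._series((10.0, 20.0, 30.0), truth))
        assert fit.slope == pytest.approx(truth.slope, rel=1e-10)
        assert fit.intercept == pytest.approx(truth.intercept, rel=1e-10)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_two_points_interpolate_exactly(self):
        fit, r2 = g.fit_fpm_line(
            self._series((10.0, 30.0), g.FractionalPlasmaLine())
        )
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_week0_records_are_excluded(self):
        truth = g.FractionalPlasmaLine()
        with_w0 = g.fit_fpm_line(
            self._series((10.0, 20.0, 30.0), truth, include_week0=True)
        )
        without = g.fit_fpm_line(self._series((10.0, 20.0, 30.0), truth))
        assert with_w0[0] == without[0]

    def test_underdetermined(self):
        with pytest.raises(UnderdeterminedError):
            g.fit_fpm_line(self._series((20.0,), g.FractionalPlasmaLine()))
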