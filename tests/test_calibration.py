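"""Least-squares calibration: objective, variants, parameter recovery.

The steady-state model depends on (k_i, a, b, c, glucose) only through
k_i / ((1-a) + b·(w-25)_+ + c·G·1{G>thr}), so fits are assessed on the
identifiable combinations k_i/(1-a), b/(1-a) and a − c·G, plus the
fixed-point property that a fit initialized at the generating values
returns them unchanged.
"""

import numpy as np
import pytest

import gestag as g
from gestag.calibrate import PARAM_NAMES, variant_defaults
from gestag.errors import IdentifiabilityError


def make_fixture(truth, group="normal", noise_sd=0.0, seed=1):
    series, echo = g.recovery_fixture(
        truth, noise_sd=noise_sd, seed=seed, group=group, n_subjects=1
    )
    return series, echo


@pytest.fixture
def normal_truth():
    return g.KineticParams(
        k_i=5.16, glucose=5.0, reabs=g.ReabsorptionParams(a=0.99825, b=5.78e-5)
    )


@pytest.fixture
def diabetic_truth():
    return g.KineticParams(
        k_i=5.0,
        glucose=9.5,
        reabs=g.ReabsorptionParams(a=0.997, b=5.78e-5, c=0.00029),
    )


class TestSSE:
    def test_zero_when_prediction_matches(self, normal_params, week_grid):
        traj = g.trajectory(week_grid, normal_params)
        rows = [
            ("m", "normal", w, "ag", c)
            for w, c in zip(traj.weeks, traj.concentration)
        ]
        obs = g.LongitudinalSeries.from_records(rows)
        assert g.sse(traj, obs) == pytest.approx(0.0, abs=1e-20)

    def test_single_week_squared_difference(self, normal_params):
        traj = g.trajectory(np.array([10.0, 20.0]), normal_params)
        obs = g.LongitudinalSeries.from_records(
            [("m", "normal", 10.0, "ag", traj.concentration[0] + 2.0)]
        )
        assert g.sse(traj, obs) == pytest.approx(4.0)

    def test_hand_residuals(self, normal_params):
        traj = g.trajectory(np.array([10.0, 20.0, 30.0]), normal_params)
        resid = np.array([1.0, -2.0, 3.0])
        rows = [
            ("m", "normal", w, "ag", c + r)
            for w, c, r in zip(traj.weeks, traj.concentration, resid)
        ]
        obs = g.LongitudinalSeries.from_records(rows)
        assert g.sse(traj, obs) == pytest.approx(14.0)

    def test_empty_observations_error(self, normal_params, week_grid):
        traj = g.trajectory(week_grid, normal_params)
        obs = g.LongitudinalSeries.from_records(
            [("m", "normal", 10.0, "gfr", 120.0)]
        )
        with pytest.raises(ValueError):
            g.sse(traj, obs)


class TestVariantDefaults:
    def test_normal_adjusted_nominal_values(self):
        spec = variant_defaults("normal_adjusted")
        assert spec.free == ()
        assert spec.fixed["k_i"] == 5.0 and spec.fixed["a"] == 0.9984
        assert spec.fixed["b"] == 0.0

    def test_diabetic_adjusted_uses_representative_glucose(self):
        spec = variant_defaults("diabetic_adjusted")
        assert spec.fixed["glucose"] == 8.9
        assert spec.reabs_form == "stickle"
        assert spec.group == "gdm_dm"

    def test_diabetic_rtime_fixes_input_rate(self):
        spec = variant_defaults("diabetic_bestfit_rtime")
        assert spec.fixed["k_i"] == 5.0
        assert set(spec.free) == {"a", "b", "glucose"}
        assert spec.fixed["c"] == 0.0026

    def test_all_variants_cover_parameters(self):
        for variant in g.VARIANTS:
            spec = variant_defaults(variant)
            assert set(spec.free) | set(spec.fixed) == set(PARAM_NAMES)
            assert spec.tol == 1e-5

    def test_unknown_variant(self):
        with pytest.raises(ValueError):
            variant_defaults("bogus")


class TestCalibrate:
    def test_no_free_parameters_evaluates_fixed_model(self, normal_truth):
        series, _ = make_fixture(normal_truth)
        spec = variant_defaults("normal_adjusted")
        fit = g.calibrate(series, spec)
        assert fit.converged
        assert fit.estimates == spec.fixed
        assert fit.sse > 0  # nominal model differs from the rtime truth

    def test_joint_c_glucose_refused(self, normal_truth):
        series, _ = make_fixture(normal_truth)
        base = variant_defaults("diabetic_bestfit_rtime")
        spec = g.FitSpec(
            variant=base.variant,
            free=("a", "b", "c", "glucose"),
            fixed={"k_i": 5.0},
            init={"a": 0.9984, "b": 0.0, "c": 0.0026, "glucose": 8.9},
            group="normal",
        )
        with pytest.raises(IdentifiabilityError):
            g.calibrate(series, spec)

    def test_normal_rtime_recovery_identifiable_combinations(self, normal_truth):
        series, echo = make_fixture(normal_truth)
        fit = g.calibrate(series, variant_defaults("normal_bestfit_rtime"))
        e = fit.estimates
        assert fit.sse <= 1e-10
        assert e["k_i"] / (1 - e["a"]) == pytest.approx(
            echo["k_i"] / (1 - echo["a"]), rel=1e-3
        )
        assert e["b"] / (1 - e["a"]) == pytest.approx(
            echo["b"] / (1 - echo["a"]), rel=1e-3
        )

    def test_normal_rtime_truth_is_fixed_point(self, normal_truth):
        series, echo = make_fixture(normal_truth)
        base = variant_defaults("normal_bestfit_rtime")
        spec = g.FitSpec(
            variant=base.variant,
            free=base.free,
            fixed=base.fixed,
            init={"k_i": echo["k_i"], "a": echo["a"], "b": echo["b"]},
            group="normal",
        )
        fit = g.calibrate(series, spec)
        assert fit.sse <= 1e-18
        for name in base.free:
            assert fit.estimates[name] == pytest.approx(echo[name], rel=1e-6)

    def test_diabetic_rtime_recovery_identifiable_combinations(self, diabetic_truth):
        series, echo = make_fixture(diabetic_truth, group="gdm_dm")
        base = variant_defaults("diabetic_bestfit_rtime")
        spec = g.FitSpec(
            variant=base.variant,
            free=base.free,
            fixed={"k_i": 5.0, "c": echo["c"]},
            init=base.init,
            group="gdm_dm",
        )
        fit = g.calibrate(series, spec)
        e = fit.estimates
        assert fit.sse <= 1e-10
        assert e["a"] - echo["c"] * e["glucose"] == pytest.approx(
            echo["a"] - echo["c"] * echo["glucose"], rel=1e-6
        )
        assert e["b"] == pytest.approx(echo["b"], rel=1e-3)

    def test_objective_history_non_increasing(self, normal_truth):
        series, _ = make_fixture(normal_truth)
        fit = g.calibrate(series, variant_defaults("normal_bestfit_rtime"))
        hist = np.array(fit.history)
        finite = hist[np.isfinite(hist)]
        assert np.all(np.diff(finite) <= 0)

    def test_freeing_more_parameters_never_fits_worse(self, normal_truth):
        series, _ = make_fixture(normal_truth)
        sub = g.calibrate(series, variant_defaults("normal_bestfit"))
        sup = g.calibrate(series, variant_defaults("normal_bestfit_rtime"))
        assert sup.sse <= sub.sse + 1e-12

    def test_row_order_invariance(self, normal_truth):
        series, _ = make_fixture(normal_truth)
        df = series.df
        shuffled = g.LongitudinalSeries(
            df.sample(frac=1.0, random_state=7).reset_index(drop=True)
        )
        a = g.calibrate(series, variant_defaults("normal_bestfit_rtime"))
        b = g.calibrate(shuffled, variant_defaults("normal_bestfit_rtime"))
        assert a.estimates == b.estimates
        assert a.sse == b.sse

    def test_estimate_converges_to_truth_as_noise_shrinks(self, normal_truth):
        """The identifiable ratio approaches truth as noise goes to 0."""
        truth_ratio = 5.16 / (1 - 0.99825)
        errs = []
        for sd in (1.0, 0.1):
            series, _ = g.recovery_fixture(
                normal_truth, noise_sd=sd, seed=11, group="normal", n_subjects=40
            )
            fit = g.calibrate(series, variant_defaults("normal_bestfit_rtime"))
            e = fit.estimates
            errs.append(abs(e["k_i"] / (1 - e["a"]) - truth_ratio) / truth_ratio)
        assert errs[1] < errs[0]
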