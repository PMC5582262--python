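"""Gestational physiology curves: GFR, plasma volume, fractional plasma mass.

Three empirical curves describe how maternal physiology changes with
gestational week ``t`` (week 0 = pre-pregnancy baseline):

* **GFR** (mL/min): concave quadratic ``a2·t² + a1·t + a0``. With the
  default coefficients the curve rises from 99.04 mL/min to a peak of
  ~155.5 mL/min at 27.1 weeks (a 1.57-fold increase) before declining.
* **Plasma volume** (mL): four-parameter sigmoid plus baseline,
  ``num / (d0 + d1·exp(sign·rate·(t − t_mid))) + offset``. The ``sign``
  flag selects the exponent convention; the default (+1) keeps the
  published closed form, whose large-week limit is the ``offset``.
* **Fractional plasma mass** (unitless): the fraction of body-mass gain
  attributable to plasma gain, a declining line ``slope·t + intercept``
  constrained to (0, 1].

The quadratic and the line are fit in closed form (ordinary least
squares); the sigmoid requires iterative nonlinear least squares and is
initialized from the published parameter values by default. Fit quality
is reported as the standard coefficient of determination
R² = 1 − SS_res/SS_tot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    DegenerateCurveError,
    FitFailureError,
    PhysioRangeError,
    UnderdeterminedError,
    ZeroVarianceError,
)
from .series import LongitudinalSeries, check_week

__all__ = [
    "GFRQuadratic",
    "PlasmaVolumeSigmoid",
    "FractionalPlasmaLine",
    "PhysioCurveSet",
    "default_curves",
    "eval_gfr",
    "gfr_peak",
    "eval_plasma_volume",
    "compute_fpm",
    "eval_fpm",
    "fit_gfr_quadratic",
    "fit_plasma_volume_sigmoid",
    "fit_fpm_line",
    "r_squared",
]


@dataclass(frozen=True)
class GFRQuadratic:
    """Quadratic GFR(t) in mL/min; coefficients in mL/min per week^k."""

    a2: float = -0.077
    a1: float = 4.17
    a0: float = 99.04

    def __post_init__(self):
        if self.a0 <= 0:
            raise DegenerateCurveError("GFR intercept a0 must be positive")


@dataclass(frozen=True)
class PlasmaVolumeSigmoid:
    """Sigmoidal plasma volume V(t) in mL.

    ``sign=+1`` keeps the published exponent convention (volume approaches
    ``offset`` at large t); ``sign=-1`` flips the sigmoid so volume rises
    with gestation, matching the direction of the underlying cohort data.
    The steady-state 1,5-AG model is invariant to this choice because
    plasma volume cancels there.
    """

    num: float = 796.2
    d0: float = 0.62
    d1: float = 4.4
    rate: float = 0.21
    t_mid: float = 9.2
    offset: float = 2378.0
    sign: int = 1

    def __post_init__(self):
        if self.d0 <= 0 or self.d1 <= 0:
            raise DegenerateCurveError("sigmoid denominator constants must be positive")
        if self.offset <= 0:
            raise DegenerateCurveError("plasma-volume offset must be positive")
        if self.sign not in (1, -1):
            raise DegenerateCurveError("sign convention must be +1 or -1")


@dataclass(frozen=True)
class FractionalPlasmaLine:
    """Linear fractional plasma mass f(t), required to stay in (0, 1]."""

    slope: float = -0.006
    intercept: float = 0.32


@dataclass(frozen=True)
class PhysioCurveSet:
    """The three fitted gestational curves used by the kinetic model."""

    gfr: GFRQuadratic = field(default_factory=GFRQuadratic)
    plasma_volume: PlasmaVolumeSigmoid = field(default_factory=PlasmaVolumeSigmoid)
    fpm: FractionalPlasmaLine = field(default_factory=FractionalPlasmaLine)


def default_curves() -> PhysioCurveSet:
    """Curve set at the published default coefficients."""
    return PhysioCurveSet()


def _as_week(week):
    check_week(week)
    return np.asarray(week, dtype=float)


def _scalar_or_array(x, week):
    return float(x) if np.isscalar(week) or np.ndim(week) == 0 else x


def eval_gfr(curve: GFRQuadratic, week) -> float | np.ndarray:
    """GFR in mL/min at gestational week(s); errors on non-positive values."""
    w = _as_week(week)
    g = curve.a2 * w**2 + curve.a1 * w + curve.a0
    if np.any(g <= 0):
        raise DegenerateCurveError(f"GFR non-positive at week {week!r}")
    return _scalar_or_array(g, week)


def gfr_peak(curve: GFRQuadratic) -> tuple[float, float]:
    """Vertex of a concave GFR quadratic.

    Returns ``(peak_week, fold_increase)`` where ``fold_increase`` is
    GFR at the vertex over GFR at week 0.
    """
    if curve.a2 >= 0:
        raise DegenerateCurveError("no interior maximum: a2 must be negative")
    peak_week = -curve.a1 / (2.0 * curve.a2)
    peak_val = curve.a2 * peak_week**2 + curve.a1 * peak_week + curve.a0
    if peak_val <= 0:
        raise DegenerateCurveError("GFR non-positive at the vertex")
    fold = peak_val / curve.a0
    return peak_week, fold


def eval_plasma_volume(curve: PlasmaVolumeSigmoid, week) -> float | np.ndarray:
    """Plasma volume in mL at gestational week(s)."""
    w = _as_week(week)
    v = curve.num / (
        curve.d0 + curve.d1 * np.exp(curve.sign * curve.rate * (w - curve.t_mid))
    ) + curve.offset
    if np.any(v <= 0):
        raise PhysioRangeError(f"plasma volume non-positive at week {week!r}")
    return _scalar_or_array(v, week)


def compute_fpm(delta_plasma_mass: float, delta_total_mass: float) -> float:
    """Fractional plasma mass: plasma-mass gain over total-mass gain (kg/kg).

    Undefined at the pre-pregnancy baseline where both gains are zero.
    """
    if delta_total_mass <= 0:
        raise PhysioRangeError(
            "fractional plasma mass undefined: total mass gain must be positive"
        )
    return delta_plasma_mass / delta_total_mass


def eval_fpm(line: FractionalPlasmaLine, week) -> float | np.ndarray:
    """Fractional plasma mass at week(s); must stay within (0, 1]."""
    w = _as_week(week)
    f = line.slope * w + line.intercept
    if np.any(f <= 0) or np.any(f > 1):
        raise PhysioRangeError(
            f"fractional plasma mass outside (0, 1] at week {week!r}"
        )
    return _scalar_or_array(f, week)


def r_squared(observed, predicted) -> float:
    """Coefficient of determination, 1 - SS_res/SS_tot."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1 or obs.size < 2:
        raise ValueError("observed and predicted must be equal-length 1-d, n >= 2")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise ZeroVarianceError("R^2 undefined: observations are constant")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def _fit_r2(values, fitted) -> float:
    """R^2 for fit reporting; a perfect fit of constant data counts as 1."""
    values = np.asarray(values, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    try:
        return r_squared(values, fitted)
    except ZeroVarianceError:
        if np.allclose(values, fitted, rtol=0, atol=1e-12 * max(1.0, abs(values[0]))):
            return 1.0
        raise


def fit_gfr_quadratic(data: LongitudinalSeries) -> tuple[GFRQuadratic, float]:
    """Least-squares quadratic fit to all GFR records (closed form)."""
    df = data.subset(variable="gfr")
    weeks = df["week"].to_numpy(dtype=float)
    values = df["value"].to_numpy(dtype=float)
    if np.unique(weeks).size < 3:
        raise UnderdeterminedError("quadratic GFR fit needs >= 3 distinct weeks")
    a2, a1, a0 = np.polyfit(weeks, values, 2)
    curve = GFRQuadratic(a2=float(a2), a1=float(a1), a0=float(a0))
    fitted = a2 * weeks**2 + a1 * weeks + a0
    return curve, _fit_r2(values, fitted)


def fit_plasma_volume_sigmoid(
    data: LongitudinalSeries,
    init: PlasmaVolumeSigmoid | None = None,
    max_nfev: int = 20000,
) -> tuple[PlasmaVolumeSigmoid, float]:
    """Nonlinear least-squares sigmoid fit to all plasma-volume records.

    The exponent sign convention is taken from ``init`` and held fixed;
    the six remaining parameters are free. Initialized at the published
    coefficients unless ``init`` is given.
    """
    if init is None:
        init = PlasmaVolumeSigmoid()
    df = data.subset(variable="plasma_volume")
    weeks = df["week"].to_numpy(dtype=float)
    values = df["value"].to_numpy(dtype=float)
    if np.unique(weeks).size < 6:
        raise UnderdeterminedError(
            "sigmoid plasma-volume fit needs >= 6 distinct weeks (six parameters)"
        )
    sign = init.sign

    def model(x, w):
        num, d0, d1, rate, t_mid, offset = x
        return num / (d0 + d1 * np.exp(sign * rate * (w - t_mid))) + offset

    x0 = np.array([init.num, init.d0, init.d1, init.rate, init.t_mid, init.offset])
    res = least_squares(
        lambda x: model(x, weeks) - values, x0, max_nfev=max_nfev, xtol=1e-14,
        ftol=1e-14, gtol=1e-14,
    )
    if not res.success:
        raise FitFailureError(
            f"sigmoid fit did not converge: {res.message}", n_iter=res.nfev
        )
    num, d0, d1, rate, t_mid, offset = (float(v) for v in res.x)
    curve = PlasmaVolumeSigmoid(
        num=num, d0=d0, d1=d1, rate=rate, t_mid=t_mid, offset=offset, sign=sign
    )
    return curve, _fit_r2(values, model(res.x, weeks))


def fit_fpm_line(data: LongitudinalSeries) -> tuple[FractionalPlasmaLine, float]:
    """Ordinary least-squares line through per-subject-week mass-gain ratios.

    Fractions are computed per (subject, week) from paired plasma- and
    total-mass gains via :func:`compute_fpm`; week 0 is always excluded
    (the ratio is 0/0 at baseline).
    """
    df = data.subset()
    mass = df[df["variable"].isin(("plasma_mass_gain", "total_mass_gain"))]
    wide = mass.pivot_table(
        index=["subject_id", "week"], columns="variable", values="value"
    )
    if (
        "plasma_mass_gain" not in wide.columns
        or "total_mass_gain" not in wide.columns
    ):
        raise UnderdeterminedError("need paired plasma and total mass gains")
    wide = wide.dropna(subset=["plasma_mass_gain", "total_mass_gain"])
    wide = wide[wide.index.get_level_values("week") > 0]
    weeks = wide.index.get_level_values("week").to_numpy(dtype=float)
    if np.unique(weeks).size < 2:
        raise UnderdeterminedError("fractional-plasma-mass line needs >= 2 weeks > 0")
    fracs = np.array(
        [
            compute_fpm(p, t)
            for p, t in zip(wide["plasma_mass_gain"], wide["total_mass_gain"])
        ]
    )
    slope, intercept = np.polyfit(weeks, fracs, 1)
    line = FractionalPlasmaLine(slope=float(slope), intercept=float(intercept))
    return line, _fit_r2(fracs, slope * weeks + intercept)
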