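"""Least-squares calibration of the kinetic model to 1,5-AG group means.

Six model variants mirror the published fitting workflow, three per
cohort (normal / diabetic):

* ``*_adjusted`` — no free parameters; the nominal model evaluated
  against the data (k_i = 5 mg/day, classic glucose-only reabsorption).
* ``*_bestfit`` — reabsorption constant in gestational time; normal frees
  (k_i, a), diabetic frees (k_i, glucose) under the glucose-only form.
* ``*_bestfit_rtime`` — reabsorption additionally declines after week 25;
  normal frees (k_i, a, b), diabetic fixes k_i = 5 and frees
  (a, b, glucose) with the glucose sensitivity c held fixed.

The objective is the unweighted sum of squared differences between the
model steady-state trajectory and the observed week-binned group means
(µg/mL). Minimization uses derivative-free Nelder–Mead simplex search
with a function-value termination tolerance of 1e-5 and box bounds.

Identifiability
---------------
At steady state the model depends on the calibrated parameters only
through ``k_i / ((1−a) + b·(w−25)_+ + c·G·1{G>thr})``. Consequences:

* c and G enter only as the product c·G — specs with both free are
  rejected outright.
* (k_i, a, b) carry an exact one-dimensional scaling ridge: only
  k_i/(1−a) and b/(1−a) are identifiable from concentration data.
* With c fixed, a and c·G trade off additively: only a − c·G is
  identifiable when both a and G are free.

The simplex search converges to *a* point on the optimal ridge; which
point depends on the initialization. Fits therefore report point
estimates whose identifiable combinations are well determined, while the
individual coordinates along a ridge inherit the initialization (this is
also the likely origin of the published "best-fit k_i = 2.73 versus the
expected 5"). See docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .curves import PhysioCurveSet, default_curves
from .errors import GestagError, IdentifiabilityError
from .kinetics import (
    KineticParams,
    ReabsorptionParams,
    StickleParams,
    Trajectory,
    trajectory,
)
from .series import LongitudinalSeries

__all__ = [
    "PARAM_NAMES",
    "VARIANTS",
    "DEFAULT_BOUNDS",
    "FitSpec",
    "FitResult",
    "sse",
    "variant_defaults",
    "calibrate",
]

PARAM_NAMES = ("k_i", "a", "b", "c", "glucose")

VARIANTS = (
    "normal_adjusted",
    "normal_bestfit",
    "normal_bestfit_rtime",
    "diabetic_adjusted",
    "diabetic_bestfit",
    "diabetic_bestfit_rtime",
)

# wide boxes enclosing every published value
DEFAULT_BOUNDS = {
    "k_i": (0.1, 50.0),
    "a": (0.9, 0.99999),
    "b": (0.0, 0.01),
    "c": (0.0, 0.01),
    "glucose": (1.0, 30.0),
}


@dataclass(frozen=True)
class FitSpec:
    """Which parameters to fit, from where, and within which bounds."""

    variant: str
    free: tuple[str, ...]
    fixed: dict[str, float]
    init: dict[str, float]
    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )
    tol: float = 1e-5
    reabs_form: str = "gestational"
    group: str = "normal"

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        free, fixed = set(self.free), set(self.fixed)
        if free & fixed:
            raise ValueError(f"parameters both free and fixed: {free & fixed}")
        if free | fixed != set(PARAM_NAMES):
            raise ValueError(
                f"free + fixed must cover exactly {PARAM_NAMES}, "
                f"got {sorted(free | fixed)}"
            )
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        for name in self.free:
            lo, hi = self.bounds[name]
            if not lo <= self.init[name] <= hi:
                raise ValueError(
                    f"init for {name} ({self.init[name]}) outside bounds [{lo}, {hi}]"
                )


@dataclass(frozen=True)
class FitResult:
    """Calibrated estimates with objective value and convergence metadata.

    ``history`` is the best-so-far objective after each evaluation — a
    non-increasing sequence by construction.
    """

    estimates: dict[str, float]
    sse: float
    n_eval: int
    converged: bool
    spec: FitSpec
    history: tuple[float, ...] = ()

    def __post_init__(self):
        if self.sse < 0:
            raise ValueError("sse must be non-negative")


def sse(predicted: Trajectory, observed: LongitudinalSeries, group: str | None = None) -> float:
    """Unweighted sum of squared residuals against week-binned 1,5-AG means.

    Observed records (variable ``ag``, optionally one group) are averaged
    per week; the trajectory is linearly interpolated at each observed
    week, which must lie within the trajectory grid.
    """
    df = observed.subset(variable="ag", group=group)
    if df.empty:
        raise ValueError("no 1,5-AG observations to compare against")
    means = df.groupby("week")["value"].mean()
    weeks = means.index.to_numpy(dtype=float)
    lo, hi = predicted.weeks[0], predicted.weeks[-1]
    if weeks.min() < lo or weeks.max() > hi:
        raise ValueError("observed weeks fall outside the trajectory grid")
    pred = np.interp(weeks, predicted.weeks, predicted.concentration)
    return float(np.sum((pred - means.to_numpy()) ** 2))


def variant_defaults(variant: str, curves: PhysioCurveSet | None = None) -> FitSpec:
    """Published default specification for each fitting variant."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    nominal = {"k_i": 5.0, "a": 0.9984, "b": 0.0, "c": 0.0026, "glucose": 5.0}
    group = "normal" if variant.startswith("normal") else "gdm_dm"
    if group == "gdm_dm":
        nominal["glucose"] = 8.9
    free: tuple[str, ...]
    reabs_form = "gestational"
    if variant == "normal_adjusted":
        free = ()
    elif variant == "normal_bestfit":
        free = ("k_i", "a")
    elif variant == "normal_bestfit_rtime":
        free = ("k_i", "a", "b")
    elif variant == "diabetic_adjusted":
        free = ()
        reabs_form = "stickle"
    elif variant == "diabetic_bestfit":
        free = ("k_i", "glucose")
        reabs_form = "stickle"
    else:  # diabetic_bestfit_rtime
        free = ("a", "b", "glucose")
    fixed = {k: v for k, v in nominal.items() if k not in free}
    init = {k: nominal[k] for k in free}
    return FitSpec(
        variant=variant,
        free=free,
        fixed=fixed,
        init=init,
        tol=1e-5,
        reabs_form=reabs_form,
        group=group,
    )


def params_from_theta(
    theta: dict[str, float],
    curves: PhysioCurveSet,
    reabs_form: str = "gestational",
) -> KineticParams:
    """Assemble KineticParams from a flat parameter dictionary."""
    if reabs_form == "stickle":
        stickle = StickleParams(
            slope=theta["c"], intercept=1.018, baseline=theta["a"], threshold=7.4
        )
        return KineticParams(
            k_i=theta["k_i"],
            glucose=theta["glucose"],
            curves=curves,
            reabs_form="stickle",
            stickle=stickle,
        )
    reabs = ReabsorptionParams(a=theta["a"], b=theta["b"], c=theta["c"])
    return KineticParams(
        k_i=theta["k_i"], glucose=theta["glucose"], curves=curves, reabs=reabs
    )


def calibrate(
    data: LongitudinalSeries,
    spec: FitSpec,
    curves: PhysioCurveSet | None = None,
    maxiter: int = 5000,
) -> FitResult:
    """Minimize the sum of squared residuals over the spec's free parameters.

    Deterministic given data and spec (simplex search from ``spec.init``,
    no random restarts); the returned objective never exceeds the
    objective at the initialization. Non-convergence returns the best
    point found, flagged ``converged=False``.
    """
    if curves is None:
        curves = default_curves()
    if "c" in spec.free and "glucose" in spec.free:
        raise IdentifiabilityError(
            "c and glucose enter the model only as the product c*glucose; "
            "fix one of them"
        )
    df = data.subset(variable="ag", group=spec.group)
    if df.empty:
        raise ValueError(f"no 1,5-AG records for group {spec.group!r}")
    means = df.groupby("week")["value"].mean().sort_index()
    weeks = means.index.to_numpy(dtype=float)
    if weeks.size < len(spec.free) + 1:
        raise ValueError(
            f"need at least {len(spec.free) + 1} distinct weeks, got {weeks.size}"
        )
    target = means.to_numpy(dtype=float)

    n_eval = 0
    history: list[float] = []
    best: list = [np.inf, None]

    def objective(x: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        theta = dict(spec.fixed)
        theta.update(zip(spec.free, x))
        try:
            p = params_from_theta(theta, curves, spec.reabs_form)
            pred = trajectory(weeks, p).concentration
            val = float(np.sum((pred - target) ** 2))
        except (GestagError, ValueError):
            val = np.inf
        if val < best[0]:
            best[0], best[1] = val, np.array(x, dtype=float)
        history.append(best[0] if np.isfinite(best[0]) else val)
        return val

    if not spec.free:
        val = objective(np.array([]))
        return FitResult(
            estimates=dict(spec.fixed),
            sse=val,
            n_eval=n_eval,
            converged=True,
            spec=spec,
            history=tuple(history),
        )

    x0 = np.array([spec.init[name] for name in spec.free], dtype=float)
    bounds = [spec.bounds[name] for name in spec.free]
    res = minimize(
        objective,
        x0,
        method="Nelder-Mead",
        bounds=bounds,
        options={
            "fatol": spec.tol,
            "xatol": 1e-10,
            "maxiter": maxiter,
            "maxfev": 4 * maxiter,
        },
    )
    x_best = best[1] if best[1] is not None else res.x
    estimates = dict(spec.fixed)
    estimates.update({k: float(v) for k, v in zip(spec.free, x_best)})
    return FitResult(
        estimates=estimates,
        sse=float(best[0]),
        n_eval=n_eval,
        converged=bool(res.success),
        spec=spec,
        history=tuple(history),
    )
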