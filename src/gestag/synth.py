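"""Seeded synthetic cohorts emulating the literature datasets behind the model.

Four cohort kinds mirror the source studies the physiological curves and
the 1,5-AG comparisons were built from:

* ``gfr`` — 25 subjects, inulin-clearance GFR at weeks {0, 16, 26, 36},
  Gaussian noise SD 21.2 mL/min around the quadratic truth curve.
* ``plasma_volume`` — 69 subjects at seven visits {0, 8, 14, 20, 26, 32,
  38}, noise SD 52.3 mL around the sigmoid truth curve.
* ``body_composition`` — 27 subjects at weeks {0, 11, 23, 35}; emits
  paired plasma- and total-mass gains consistent with the truth
  fractional-plasma-mass line (noise SD 0.12 applied on the fraction
  scale; total gain follows a 0.3125 kg/week line, i.e. 12.5 kg at term).
* ``ag_series`` — longitudinal serum 1,5-AG generated from the
  steady-state kinetic model every 2 weeks from 6 to 38, noise SD
  3 µg/mL; default cohort sizes 543 (normal) and 75 (GDM/DM).

Noise is Gaussian, independent across subjects and weeks, and truncated
below at 1% of the truth value so strictly positive variables stay
physical. Each subject draws from its own counter-derived substream of
the cohort seed, so outputs are reproducible bit-for-bit and per-subject
records are stable under schedule changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
import pandas as pd

from .curves import (
    FractionalPlasmaLine,
    GFRQuadratic,
    PlasmaVolumeSigmoid,
    eval_fpm,
    eval_gfr,
    eval_plasma_volume,
)
from .kinetics import KineticParams, steady_state_closed_form
from .series import LongitudinalSeries

__all__ = [
    "COHORT_KINDS",
    "AG_WEEKS",
    "CohortSpec",
    "default_cohort",
    "generate",
    "group_means",
    "means_series",
    "recovery_fixture",
    "truth_to_dict",
]

COHORT_KINDS = ("gfr", "plasma_volume", "body_composition", "ag_series")

#: default 1,5-AG visit schedule: every 2 weeks from 6 to 38
AG_WEEKS = tuple(float(w) for w in range(6, 40, 2))

#: total-body-mass gain slope, kg per gestational week (12.5 kg at 40 wk)
TOTAL_GAIN_RATE = 0.3125

_KIND_DEFAULTS = {
    "gfr": dict(n_subjects=25, weeks=(0.0, 16.0, 26.0, 36.0), noise_sd=21.2),
    "plasma_volume": dict(
        n_subjects=69, weeks=(0.0, 8.0, 14.0, 20.0, 26.0, 32.0, 38.0), noise_sd=52.3
    ),
    "body_composition": dict(
        n_subjects=27, weeks=(0.0, 11.0, 23.0, 35.0), noise_sd=0.12
    ),
    "ag_series": dict(n_subjects=543, weeks=AG_WEEKS, noise_sd=3.0),
}

Truth = Union[GFRQuadratic, PlasmaVolumeSigmoid, FractionalPlasmaLine, KineticParams]


@dataclass(frozen=True)
class CohortSpec:
    """Specification of one synthetic cohort."""

    kind: str
    n_subjects: int
    weeks: tuple[float, ...]
    noise_sd: float
    truth: Truth
    group: str = "normal"
    seed: int = 0

    def __post_init__(self):
        if self.kind not in COHORT_KINDS:
            raise ValueError(f"unknown cohort kind {self.kind!r}")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if len(self.weeks) == 0:
            raise ValueError("visit schedule must be non-empty")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def default_cohort(kind: str, group: str = "normal", seed: int = 0, **overrides) -> CohortSpec:
    """Cohort spec at the study-condition defaults for ``kind``."""
    if kind not in COHORT_KINDS:
        raise ValueError(f"unknown cohort kind {kind!r}")
    kw = dict(_KIND_DEFAULTS[kind])
    if kind == "gfr":
        kw["truth"] = GFRQuadratic()
    elif kind == "plasma_volume":
        kw["truth"] = PlasmaVolumeSigmoid()
    elif kind == "body_composition":
        kw["truth"] = FractionalPlasmaLine()
    else:
        glucose = 8.9 if group == "gdm_dm" else 5.0
        kw["truth"] = KineticParams(glucose=glucose)
        if group == "gdm_dm":
            kw["n_subjects"] = 75
    kw.update(overrides)
    return CohortSpec(kind=kind, group=group, seed=seed, **kw)


def _truth_value(spec: CohortSpec, week: float) -> float:
    if spec.kind == "gfr":
        return eval_gfr(spec.truth, week)
    if spec.kind == "plasma_volume":
        return eval_plasma_volume(spec.truth, week)
    if spec.kind == "body_composition":
        return eval_fpm(spec.truth, week)
    return steady_state_closed_form(week, spec.truth)


def generate(spec: CohortSpec) -> LongitudinalSeries:
    """Draw one synthetic cohort; bit-for-bit reproducible given the seed."""
    streams = np.random.SeedSequence(spec.seed).spawn(spec.n_subjects)
    var = {"gfr": "gfr", "plasma_volume": "plasma_volume", "ag_series": "ag"}.get(
        spec.kind
    )
    rows = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        sid = f"{spec.kind}_{spec.group}_{i:04d}"
        for week in spec.weeks:
            if spec.kind == "body_composition":
                total = TOTAL_GAIN_RATE * week
                if week == 0:
                    rows.append((sid, spec.group, week, "plasma_mass_gain", 0.0, np.nan))
                    rows.append((sid, spec.group, week, "total_mass_gain", 0.0, np.nan))
                    continue
                truth_frac = _truth_value(spec, week)
                frac = truth_frac + rng.normal(0.0, spec.noise_sd)
                frac = min(max(frac, 0.01 * truth_frac), 1.0)
                rows.append(
                    (sid, spec.group, week, "plasma_mass_gain", frac * total, np.nan)
                )
                rows.append((sid, spec.group, week, "total_mass_gain", total, np.nan))
            else:
                truth = _truth_value(spec, week)
                value = truth + rng.normal(0.0, spec.noise_sd)
                value = max(value, 0.01 * truth)
                rows.append((sid, spec.group, week, var, value, np.nan))
    return LongitudinalSeries(
        pd.DataFrame(
            rows, columns=["subject_id", "group", "week", "variable", "value", "sd"]
        )
    )


def group_means(data: LongitudinalSeries) -> pd.DataFrame:
    """Arithmetic mean, sample SD (ddof=1, NaN for n=1) and n per
    (group, variable, week)."""
    df = data.df
    out = (
        df.groupby(["group", "variable", "week"])["value"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
        .reset_index()
    )
    return out


def means_series(data: LongitudinalSeries) -> LongitudinalSeries:
    """Group means repackaged as a LongitudinalSeries (one pseudo-subject
    per group), the shape the calibration stage consumes."""
    gm = group_means(data)
    rows = [
        (f"mean_{r.group}", r.group, r.week, r.variable, r.mean, r.sd)
        for r in gm.itertuples()
    ]
    return LongitudinalSeries.from_records(rows)


def truth_to_dict(truth: KineticParams) -> dict:
    """JSON-serializable echo of generating kinetic parameters."""
    return {
        "k_i": truth.k_i,
        "glucose": truth.glucose,
        "a": truth.reabs.a,
        "b": truth.reabs.b,
        "c": truth.reabs.c,
        "g_threshold": truth.reabs.g_threshold,
        "t_break": truth.reabs.t_break,
        "reabs_form": truth.reabs_form,
        "r_const": truth.r_const,
    }


def recovery_fixture(
    truth: KineticParams,
    weeks: tuple[float, ...] = AG_WEEKS,
    noise_sd: float = 0.0,
    seed: int = 0,
    group: str = "normal",
    n_subjects: int | None = None,
) -> tuple[LongitudinalSeries, dict]:
    """1,5-AG cohort from the steady-state model, with the generating
    parameters echoed for parameter-recovery assertions."""
    if n_subjects is None:
        n_subjects = 75 if group == "gdm_dm" else 543
    spec = CohortSpec(
        kind="ag_series",
        n_subjects=n_subjects,
        weeks=tuple(weeks),
        noise_sd=noise_sd,
        truth=truth,
        group=group,
        seed=seed,
    )
    return generate(spec), truth_to_dict(truth)
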