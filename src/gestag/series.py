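"""Longitudinal measurement container shared by every pipeline stage.

A :class:`LongitudinalSeries` holds subject- or group-level gestational
measurements in long format: one row per (subject, week, variable). The
five recognised variables are

=================   =======================================  =========
variable            meaning                                  unit
=================   =======================================  =========
gfr                 glomerular filtration rate               mL/min
plasma_volume       plasma volume                            mL
plasma_mass_gain    plasma-mass gain since conception        kg
total_mass_gain     total body-mass gain since conception    kg
ag                  plasma 1,5-anhydroglucitol               µg/mL
=================   =======================================  =========

Groups are ``normal`` (non-diabetic pregnancy) and ``gdm_dm`` (gestational
diabetes and pre-existing diabetes, pooled).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError

__all__ = [
    "GROUPS",
    "VARIABLES",
    "POSITIVE_VARIABLES",
    "WEEK_MIN",
    "WEEK_MAX",
    "LongitudinalSeries",
]

GROUPS = ("normal", "gdm_dm")
VARIABLES = ("gfr", "plasma_volume", "plasma_mass_gain", "total_mass_gain", "ag")
#: variables whose values must be strictly positive
POSITIVE_VARIABLES = frozenset({"gfr", "plasma_volume", "ag"})

WEEK_MIN = 0.0
WEEK_MAX = 42.0

COLUMNS = ("subject_id", "group", "week", "variable", "value", "sd")


def check_week(week) -> None:
    """Validate gestational week(s); week 0 is the pre-pregnancy baseline."""
    from .errors import WeekRangeError

    w = np.asarray(week, dtype=float)
    if np.any(~np.isfinite(w)) or np.any(w < WEEK_MIN) or np.any(w > WEEK_MAX):
        raise WeekRangeError(
            f"gestational week must lie in [{WEEK_MIN}, {WEEK_MAX}], got {week!r}"
        )


class LongitudinalSeries:
    """Validated long-format longitudinal measurements.

    Parameters
    ----------
    df : pandas.DataFrame
        Columns ``subject_id, group, week, variable, value, sd``. ``sd`` may
        be NaN (unknown). Row order is preserved.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.reset_index(drop=True)
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing columns: {missing}")
        df = df.loc[:, list(COLUMNS)].copy()
        df["subject_id"] = df["subject_id"].astype(str)
        df["group"] = df["group"].astype(str)
        for col in ("week", "value", "sd"):
            df[col] = pd.to_numeric(df[col], errors="coerce")
        self._validate(df)
        self._df = df

    @staticmethod
    def _validate(df: pd.DataFrame) -> None:
        bad_group = ~df["group"].isin(GROUPS)
        if bad_group.any():
            raise SchemaError(
                f"unknown group label(s) {sorted(df.loc[bad_group, 'group'].unique())}"
            )
        bad_var = ~df["variable"].isin(VARIABLES)
        if bad_var.any():
            raise SchemaError(
                f"unknown variable(s) {sorted(df.loc[bad_var, 'variable'].unique())}"
            )
        if df["week"].isna().any() or df["value"].isna().any():
            rows = df.index[df["week"].isna() | df["value"].isna()].tolist()
            raise SchemaError(f"non-numeric week/value at row(s) {rows}")
        out = (df["week"] < WEEK_MIN) | (df["week"] > WEEK_MAX)
        if out.any():
            raise SchemaError(f"week outside [0, 42] at row(s) {df.index[out].tolist()}")
        pos = df["variable"].isin(POSITIVE_VARIABLES) & (df["value"] <= 0)
        if pos.any():
            raise SchemaError(
                f"non-positive value for strictly positive variable at row(s) "
                f"{df.index[pos].tolist()}"
            )
        neg_mass = df["variable"].isin(
            ("plasma_mass_gain", "total_mass_gain")
        ) & (df["value"] < 0)
        if neg_mass.any():
            raise SchemaError(
                f"negative mass gain at row(s) {df.index[neg_mass].tolist()}"
            )
        if (df["sd"].dropna() < 0).any():
            raise SchemaError("negative sd")
        dup = df.duplicated(subset=["subject_id", "week", "variable"], keep=False)
        if dup.any():
            raise SchemaError(
                f"duplicate (subject_id, week, variable) at row(s) "
                f"{df.index[dup].tolist()}"
            )
        # total gain must dominate plasma gain wherever both were measured
        mass = df[df["variable"].isin(("plasma_mass_gain", "total_mass_gain"))]
        if not mass.empty:
            wide = mass.pivot_table(
                index=["subject_id", "week"], columns="variable", values="value"
            )
            if {"plasma_mass_gain", "total_mass_gain"} <= set(wide.columns):
                both = wide.dropna(subset=["plasma_mass_gain", "total_mass_gain"])
                both = both[both.index.get_level_values("week") > 0]
                bad = both["total_mass_gain"] < both["plasma_mass_gain"]
                if bad.any():
                    raise SchemaError(
                        "total_mass_gain < plasma_mass_gain at "
                        f"{both.index[bad].tolist()}"
                    )

    @classmethod
    def from_records(
        cls, records: Iterable[Mapping | Sequence]
    ) -> "LongitudinalSeries":
        """Build from an iterable of dicts or (subject_id, group, week,
        variable, value[, sd]) tuples."""
        rows = []
        for rec in records:
            if isinstance(rec, Mapping):
                row = {c: rec.get(c, np.nan) for c in COLUMNS}
            else:
                rec = list(rec)
                if len(rec) == 5:
                    rec.append(np.nan)
                row = dict(zip(COLUMNS, rec))
            rows.append(row)
        return cls(pd.DataFrame(rows, columns=list(COLUMNS)))

    @property
    def df(self) -> pd.DataFrame:
        """Copy of the underlying frame."""
        return self._df.copy()

    def subset(self, variable: str | None = None, group: str | None = None):
        """Rows matching the given variable and/or group, as arrays."""
        df = self._df
        if variable is not None:
            df = df[df["variable"] == variable]
        if group is not None:
            df = df[df["group"] == group]
        return df.copy()

    def weeks(self, variable: str | None = None) -> np.ndarray:
        """Sorted distinct weeks (optionally for one variable)."""
        df = self.subset(variable=variable)
        return np.sort(df["week"].unique())

    def __len__(self) -> int:
        return len(self._df)

    def equals(self, other: "LongitudinalSeries") -> bool:
        a, b = self._df, other._df
        if len(a) != len(b):
            return False
        return bool(
            (a["subject_id"].values == b["subject_id"].values).all()
            and (a["group"].values == b["group"].values).all()
            and np.allclose(a["week"], b["week"])
            and np.allclose(a["value"], b["value"])
            and np.allclose(a["sd"], b["sd"], equal_nan=True)
        )

    def __repr__(self) -> str:
        return (
            f"LongitudinalSeries({len(self._df)} records, "
            f"groups={sorted(self._df['group'].unique())}, "
            f"variables={sorted(self._df['variable'].unique())})"
        )
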