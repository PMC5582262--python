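"""Tabular and configuration I/O plus run manifests.

CSV schema for longitudinal data (one row per record, header required)::

    subject_id,group,week,variable,value,sd

with ``sd`` left blank when unknown. Trajectories are written as
``week,concentration_ug_per_ml`` with a JSON sidecar carrying the full
kinetic parameter set, so a written trajectory round-trips exactly.
Curve parameters serialize as a flat key-value config (JSON or YAML)
with keys ``gfr.a2, gfr.a1, gfr.a0, pv.num, pv.d0, pv.d1, pv.rate,
pv.t_mid, pv.offset, pv.sign, fpm.slope, fpm.intercept``.

Floats are serialized with 12 significant digits throughout.
"""

from __future__ import annotations

import csv
import datetime as _dt
import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .calibrate import FitResult, FitSpec
from .curves import (
    FractionalPlasmaLine,
    GFRQuadratic,
    PhysioCurveSet,
    PlasmaVolumeSigmoid,
)
from .errors import SchemaError
from .kinetics import (
    KineticParams,
    ReabsorptionParams,
    StickleParams,
    Trajectory,
)
from .series import COLUMNS, GROUPS, VARIABLES, LongitudinalSeries

__all__ = [
    "read_series",
    "write_series",
    "write_trajectory",
    "read_trajectory",
    "write_fit",
    "read_fit",
    "curves_to_config",
    "curves_from_config",
    "load_config",
    "save_config",
    "params_to_dict",
    "params_from_dict",
    "RunManifest",
    "build_manifest",
    "write_manifest",
]


def _fmt(x: float) -> str:
    return "" if x is None or (isinstance(x, float) and math.isnan(x)) else f"{x:.12g}"


def read_series(path) -> LongitudinalSeries:
    """Read and validate a longitudinal CSV; errors name the offending row
    (1-based, excluding the header). Row order is preserved."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: empty file") from None
        if [h.strip() for h in header] != list(COLUMNS):
            raise SchemaError(
                f"{path}: header must be exactly {','.join(COLUMNS)}"
            )
        rows = []
        seen: set[tuple] = set()
        for i, raw in enumerate(reader, start=1):
            if len(raw) != len(COLUMNS):
                raise SchemaError(f"{path} row {i}: expected {len(COLUMNS)} fields")
            sid, group, week, variable, value, sd = (f.strip() for f in raw)
            if group not in GROUPS:
                raise SchemaError(f"{path} row {i}: unknown group {group!r}")
            if variable not in VARIABLES:
                raise SchemaError(f"{path} row {i}: unknown variable {variable!r}")
            try:
                week_f = float(week)
                value_f = float(value)
                sd_f = float(sd) if sd else math.nan
            except ValueError:
                raise SchemaError(f"{path} row {i}: non-numeric field") from None
            key = (sid, week_f, variable)
            if key in seen:
                raise SchemaError(
                    f"{path} row {i}: duplicate (subject_id, week, variable) {key}"
                )
            seen.add(key)
            rows.append((sid, group, week_f, variable, value_f, sd_f))
    try:
        return LongitudinalSeries(
            pd.DataFrame(rows, columns=list(COLUMNS))
        )
    except SchemaError as exc:
        raise SchemaError(f"{path}: {exc}") from None


def write_series(path, series: LongitudinalSeries) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(COLUMNS)
        for row in series.df.itertuples(index=False):
            writer.writerow(
                [
                    row.subject_id,
                    row.group,
                    _fmt(row.week),
                    row.variable,
                    _fmt(row.value),
                    _fmt(row.sd),
                ]
            )


def params_to_dict(p: KineticParams) -> dict:
    """Full kinetic parameter set as a JSON-serializable dict."""
    return {
        "k_i": p.k_i,
        "glucose": p.glucose,
        "reabs_form": p.reabs_form,
        "r_const": p.r_const,
        "reabs": {
            "a": p.reabs.a,
            "b": p.reabs.b,
            "c": p.reabs.c,
            "g_threshold": p.reabs.g_threshold,
            "t_break": p.reabs.t_break,
        },
        "stickle": {
            "slope": p.stickle.slope,
            "intercept": p.stickle.intercept,
            "baseline": p.stickle.baseline,
            "threshold": p.stickle.threshold,
        },
        "curves": curves_to_config(p.curves),
    }


def params_from_dict(d: dict) -> KineticParams:
    return KineticParams(
        k_i=d["k_i"],
        glucose=d["glucose"],
        curves=curves_from_config(d["curves"]),
        reabs=ReabsorptionParams(**d["reabs"]),
        reabs_form=d["reabs_form"],
        stickle=StickleParams(**d["stickle"]),
        r_const=d["r_const"],
    )


def write_trajectory(path, traj: Trajectory) -> None:
    """CSV (week,concentration_ug_per_ml) plus ``<path>.params.json``."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["week", "concentration_ug_per_ml"])
        for w, c in zip(traj.weeks, traj.concentration):
            writer.writerow([_fmt(float(w)), _fmt(float(c))])
    sidecar = path.with_name(path.name + ".params.json")
    sidecar.write_text(json.dumps(params_to_dict(traj.params), indent=2))


def read_trajectory(path) -> Trajectory:
    path = Path(path)
    df = pd.read_csv(path)
    if list(df.columns) != ["week", "concentration_ug_per_ml"]:
        raise SchemaError(f"{path}: unexpected trajectory columns {list(df.columns)}")
    sidecar = path.with_name(path.name + ".params.json")
    params = params_from_dict(json.loads(sidecar.read_text()))
    return Trajectory(
        weeks=df["week"].to_numpy(dtype=float),
        concentration=df["concentration_ug_per_ml"].to_numpy(dtype=float),
        params=params,
    )


def _spec_to_dict(spec: FitSpec) -> dict:
    return {
        "variant": spec.variant,
        "free": list(spec.free),
        "fixed": spec.fixed,
        "init": spec.init,
        "bounds": {k: list(v) for k, v in spec.bounds.items()},
        "tol": spec.tol,
        "reabs_form": spec.reabs_form,
        "group": spec.group,
    }


def _spec_from_dict(d: dict) -> FitSpec:
    return FitSpec(
        variant=d["variant"],
        free=tuple(d["free"]),
        fixed={k: float(v) for k, v in d["fixed"].items()},
        init={k: float(v) for k, v in d["init"].items()},
        bounds={k: (float(v[0]), float(v[1])) for k, v in d["bounds"].items()},
        tol=d["tol"],
        reabs_form=d["reabs_form"],
        group=d["group"],
    )


def write_fit(path, fit: FitResult, input_digest: str | None = None) -> None:
    """Fit result as JSON: estimates, objective, convergence metadata,
    spec echo and (optionally) a checksum of the input data file."""
    payload = {
        "estimates": fit.estimates,
        "sse": fit.sse,
        "n_eval": fit.n_eval,
        "converged": fit.converged,
        "spec": _spec_to_dict(fit.spec),
        "input_digest": input_digest,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_fit(path) -> FitResult:
    d = json.loads(Path(path).read_text())
    return FitResult(
        estimates={k: float(v) for k, v in d["estimates"].items()},
        sse=float(d["sse"]),
        n_eval=int(d["n_eval"]),
        converged=bool(d["converged"]),
        spec=_spec_from_dict(d["spec"]),
    )


CONFIG_KEYS = (
    "gfr.a2", "gfr.a1", "gfr.a0",
    "pv.num", "pv.d0", "pv.d1", "pv.rate", "pv.t_mid", "pv.offset", "pv.sign",
    "fpm.slope", "fpm.intercept",
)


def curves_to_config(curves: PhysioCurveSet) -> dict:
    """Flat key-value form of a curve set."""
    g, v, f = curves.gfr, curves.plasma_volume, curves.fpm
    return {
        "gfr.a2": g.a2, "gfr.a1": g.a1, "gfr.a0": g.a0,
        "pv.num": v.num, "pv.d0": v.d0, "pv.d1": v.d1, "pv.rate": v.rate,
        "pv.t_mid": v.t_mid, "pv.offset": v.offset, "pv.sign": v.sign,
        "fpm.slope": f.slope, "fpm.intercept": f.intercept,
    }


def curves_from_config(cfg: dict) -> PhysioCurveSet:
    """Curve set from a flat config; missing keys fall back to defaults."""
    base = curves_to_config(PhysioCurveSet())
    unknown = set(cfg) - set(CONFIG_KEYS)
    if unknown:
        raise SchemaError(f"unknown config keys: {sorted(unknown)}")
    base.update(cfg)
    return PhysioCurveSet(
        gfr=GFRQuadratic(a2=base["gfr.a2"], a1=base["gfr.a1"], a0=base["gfr.a0"]),
        plasma_volume=PlasmaVolumeSigmoid(
            num=base["pv.num"], d0=base["pv.d0"], d1=base["pv.d1"],
            rate=base["pv.rate"], t_mid=base["pv.t_mid"],
            offset=base["pv.offset"], sign=int(base["pv.sign"]),
        ),
        fpm=FractionalPlasmaLine(
            slope=base["fpm.slope"], intercept=base["fpm.intercept"]
        ),
    )


def load_config(path) -> dict:
    """Flat curve config from YAML or JSON."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        cfg = yaml.safe_load(text)
    else:
        cfg = json.loads(text)
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: config must be a flat mapping")
    return cfg


def save_config(path, cfg: dict) -> None:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(cfg, sort_keys=True))
    else:
        path.write_text(json.dumps(cfg, indent=2, sort_keys=True))


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass(frozen=True)
class RunManifest:
    """Provenance record emitted alongside every CLI output."""

    command: str
    config_digest: str | None
    input_digests: dict[str, str]
    seed: int | None
    version: str
    timestamp: str


def build_manifest(
    command: str,
    config_path=None,
    input_paths=(),
    seed: int | None = None,
) -> RunManifest:
    return RunManifest(
        command=command,
        config_digest=_sha256(config_path) if config_path else None,
        input_digests={str(p): _sha256(p) for p in input_paths},
        seed=seed,
        version=_version,
        timestamp=_dt.datetime.now(_dt.timezone.utc).isoformat(),
    )


def write_manifest(path, manifest: RunManifest) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "command": manifest.command,
                "config_digest": manifest.config_digest,
                "input_digests": manifest.input_digests,
                "seed": manifest.seed,
                "version": manifest.version,
                "timestamp": manifest.timestamp,
            },
            indent=2,
        )
    )
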