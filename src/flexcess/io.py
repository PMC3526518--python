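"""Delimited-text readers/writers, model persistence, and run manifests.

All interchange is headered CSV; a fitted model is persisted as JSON
(specification, resolved knots, θ̂ and covariance) so predictions never
require refitting.  Every CLI run writes a manifest recording the command,
input checksums, package version and seed, making reruns verifiable.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .lifetables import LifeTable
from .model import DataSummary, FittedModel, ModelSpec, ResolvedKnots
from .splines import KnotVector

__all__ = [
    "read_cohort", "write_cohort", "read_lifetable", "write_lifetable",
    "write_curves", "save_model", "load_model", "write_manifest",
]

COHORT_REQUIRED = ("id", "time", "event", "age_dx", "sex", "year_dx")


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def _check_numeric(df: pd.DataFrame, column: str, path) -> pd.Series:
    coerced = pd.to_numeric(df[column], errors="coerce")
    bad = coerced.isna() & df[column].notna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 zero-based
        raise ValueError(
            f"{path}: non-numeric value {df[column][bad.idxmax()]!r} in "
            f"column {column!r} at line {line}"
        )
    return coerced


def read_cohort(path) -> pd.DataFrame:
    """Read a wide cohort file; validates schema and numeric columns."""

    df = pd.read_csv(path)
    _require_columns(df, COHORT_REQUIRED, path)
    for col in ("time", "event", "age_dx", "year_dx"):
        df[col] = _check_numeric(df, col, path)
    if (df["time"] <= 0).any():
        line = int((df["time"] <= 0).idxmax()) + 2
        raise ValueError(f"{path}: non-positive survival time at line {line}")
    if "cause_code" not in df.columns:
        df["cause_code"] = None
    return df


def write_cohort(path, cohort: pd.DataFrame) -> None:
    cohort.to_csv(path, index=False)


def read_lifetable(path) -> LifeTable:
    """Read ``age,sex,year,cause,rate`` cells; validation in LifeTable."""

    df = pd.read_csv(path)
    _require_columns(df, LifeTable.COLUMNS, path)
    df["rate"] = _check_numeric(df, "rate", path)
    return LifeTable(df)


def write_lifetable(path, table: LifeTable) -> None:
    table.to_frame().to_csv(path, index=False)


def write_curves(path, curve) -> None:
    """Write a CrudeProbabilityCurve as tidy CSV (one row per time)."""

    out = {"time": curve.times}
    for s, vals in curve.crude.items():
        out[f"crude_{s}"] = vals
        if curve.ci and s in curve.ci:
            out[f"crude_{s}_lo"], out[f"crude_{s}_hi"] = curve.ci[s]
    # background (non-excess) causes; distinct from a stratum named "other"
    out["crude_background"] = curve.crude_other
    if curve.ci and "background" in curve.ci:
        out["crude_background_lo"], out["crude_background_hi"] = curve.ci["background"]
    out["surv"] = curve.surv
    if curve.ci and "surv" in curve.ci:
        out["surv_lo"], out["surv_hi"] = curve.ci["surv"]
    pd.DataFrame(out).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Model persistence


def _knots_to_json(kv):
    return None if kv is None else list(kv.values)


def save_model(path, model: FittedModel) -> None:
    payload = {
        "package": "flexcess",
        "version": __version__,
        "spec": {
            "baseline_df": model.spec.baseline_df,
            "shared": list(model.spec.shared),
            "cause_specific": list(model.spec.cause_specific),
            "cause_shift": model.spec.cause_shift,
            "cause_df": model.spec.cause_df,
            "tvc": [[k, v.values if isinstance(v, KnotVector) else v]
                    for k, v in model.spec.tvc],
        },
        "knots": {
            "baseline": _knots_to_json(model.knots.baseline),
            "cause": _knots_to_json(model.knots.cause),
            "tvc": [[name, list(kv.values)] for name, kv in model.knots.tvc],
        },
        "params": {"names": list(model.params.index),
                   "theta": [float(v) for v in model.params]},
        "vcov": np.asarray(model.vcov, dtype=float).tolist(),
        "loglik": model.loglik,
        "converged": model.converged,
        "n_iter": model.n_iter,
        "grad_norm": model.grad_norm,
        "reference": model.reference,
        "summary": {
            "n_subjects": model.summary.n_subjects,
            "n_rows": model.summary.n_rows,
            "strata": list(model.summary.strata),
            "events": [list(e) for e in model.summary.events],
            "person_time": model.summary.person_time,
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path) -> FittedModel:
    payload = json.loads(Path(path).read_text())
    sp = payload["spec"]
    spec = ModelSpec(
        baseline_df=sp["baseline_df"], shared=tuple(sp["shared"]),
        cause_specific=tuple(sp["cause_specific"]), cause_shift=sp["cause_shift"],
        cause_df=sp["cause_df"],
        tvc=tuple((k, KnotVector(tuple(v)) if isinstance(v, list) else v)
                  for k, v in sp["tvc"]),
    )
    kn = payload["knots"]
    knots = ResolvedKnots(
        baseline=KnotVector(tuple(kn["baseline"])),
        cause=None if kn["cause"] is None else KnotVector(tuple(kn["cause"])),
        tvc=tuple((name, KnotVector(tuple(vals))) for name, vals in kn["tvc"]),
    )
    names = payload["params"]["names"]
    sm = payload["summary"]
    return FittedModel(
        spec=spec, knots=knots,
        params=pd.Series(payload["params"]["theta"], index=names),
        vcov=pd.DataFrame(np.array(payload["vcov"]), index=names, columns=names),
        loglik=payload["loglik"], converged=payload["converged"],
        n_iter=payload["n_iter"], grad_norm=payload["grad_norm"],
        summary=DataSummary(
            n_subjects=sm["n_subjects"], n_rows=sm["n_rows"],
            strata=tuple(sm["strata"]),
            events=tuple((s, int(c)) for s, c in sm["events"]),
            person_time=sm["person_time"],
        ),
        reference=payload["reference"],
    )


# ---------------------------------------------------------------------------
# Manifests


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(out_path, command: str, inputs: dict, seed=None,
                   config: dict | None = None) -> None:
    """One JSON manifest per CLI run, alongside the outputs."""

    manifest = {
        "command": command,
        "package": "flexcess",
        "version": __version__,
        "seed": seed,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "inputs": {name: {"path": str(p), "sha256": _sha256(p)}
                   for name, p in inputs.items() if p is not None},
        "config": config or {},
    }
    if config:
        manifest["config_sha256"] = hashlib.sha256(
            json.dumps(config, sort_keys=True).encode()).hexdigest()
    Path(out_path).write_text(json.dumps(manifest, indent=1))
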