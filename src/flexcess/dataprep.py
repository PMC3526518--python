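"""Long-format expansion for joint component-specific excess-hazard models.

Fitting one likelihood over several mutually exclusive cause strata
requires each subject to appear once per stratum: a subject followed for
``t`` years contributes, on every stratum row, the same follow-up time but
a stratum-specific event flag ``d`` (1 only on the row matching the coded
cause of death), a cause indicator ``c`` (1 on every non-reference stratum
row), and the stratum's own expected rate at exit.  Shared covariate
effects then act on all rows while cause-specific effects are interactions
with ``c``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lifetables import CauseScheme, LifeTable

__all__ = ["PatientRecord", "expand_long", "truncate_reporting"]

COHORT_COLUMNS = ("id", "time", "event", "cause_code", "age_dx", "sex", "year_dx")


@dataclass
class PatientRecord:
    """One subject in wide format.

    Follow-up ``time`` is in years (convert days with /365.24); the model
    time scale is ln(years).  ``cause_code`` is the ICD underlying cause of
    death, required when ``event`` is 1.  ``entry`` supports delayed entry
    (left truncation); 0 for a cohort followed from diagnosis.
    """

    id: object
    time: float
    event: int
    cause_code: str | None
    age_dx: float
    sex: str
    year_dx: int
    covariates: dict = field(default_factory=dict)
    entry: float = 0.0

    def __post_init__(self) -> None:
        if not self.time > 0:
            raise ValueError(f"subject {self.id}: time must be > 0, got {self.time}")
        if self.event not in (0, 1):
            raise ValueError(f"subject {self.id}: event must be 0/1")
        if self.event == 1 and not self.cause_code:
            raise ValueError(f"subject {self.id}: event=1 requires a cause code")
        if not 0 <= self.entry < self.time:
            raise ValueError(f"subject {self.id}: entry must lie in [0, time)")


def _to_frame(cohort) -> pd.DataFrame:
    if isinstance(cohort, pd.DataFrame):
        df = cohort.copy()
        missing = {"id", "time", "event", "age_dx", "sex", "year_dx"} - set(df.columns)
        if missing:
            raise ValueError(f"cohort missing columns: {sorted(missing)}")
        if "cause_code" not in df.columns:
            df["cause_code"] = None
        if "entry" not in df.columns:
            df["entry"] = 0.0
        return df
    rows = []
    for rec in cohort:
        if isinstance(rec, dict):
            rec = PatientRecord(**rec)
        row = {
            "id": rec.id, "time": rec.time, "event": rec.event,
            "cause_code": rec.cause_code, "age_dx": rec.age_dx,
            "sex": rec.sex, "year_dx": rec.year_dx, "entry": rec.entry,
        }
        row.update(rec.covariates)
        rows.append(row)
    return pd.DataFrame(rows)


def expand_long(
    cohort,
    scheme: CauseScheme,
    table: LifeTable,
    reference: str | None = None,
) -> pd.DataFrame:
    """Expand a wide cohort to one row per subject per cause stratum.

    ``cohort`` may be a DataFrame with the wide cohort columns or an
    iterable of :class:`PatientRecord` / dicts.  Returns a DataFrame with
    columns ``id, stratum, c, d, time, entry, expected_rate`` plus the
    subject columns and every covariate, ordered subject-major (the
    expansion is deterministic and order-preserving).  ``c`` is 1 on all
    non-reference stratum rows (default reference: the scheme's residual
    stratum); ``d`` marks the stratum the subject's coded cause of death
    falls in.  Expected rates come from the life table at each subject's
    exit time, advancing attained age and calendar year with follow-up.
    """

    strata = list(scheme.strata)
    if reference is None:
        reference = scheme.residual
    if reference not in strata:
        raise ValueError(f"reference {reference!r} not among strata {strata}")
    wide = _to_frame(cohort)
    if wide["id"].duplicated().any():
        dup = wide.loc[wide["id"].duplicated(), "id"].iloc[0]
        raise ValueError(f"duplicate subject id {dup!r} in cohort")
    if (wide["time"] <= 0).any():
        bad = wide.loc[wide["time"] <= 0, "id"].iloc[0]
        raise ValueError(f"subject {bad!r}: time must be > 0")

    time = wide["time"].to_numpy(float)
    exit_year = (wide["year_dx"].to_numpy(int) + np.floor(time)).astype(int)
    attained = np.minimum(
        np.floor(wide["age_dx"].to_numpy(float) + time).astype(int), table.max_age
    )

    death_stratum = np.array([None] * len(wide), dtype=object)
    ev = wide["event"].to_numpy(int) == 1
    for i in np.flatnonzero(ev):
        code = wide["cause_code"].iloc[i]
        if code is None or (isinstance(code, float) and np.isnan(code)):
            raise ValueError(f"subject {wide['id'].iloc[i]!r}: event=1 without cause code")
        try:
            death_stratum[i] = scheme.classify(str(code), int(exit_year[i]))
        except ValueError as exc:
            raise ValueError(f"subject {wide['id'].iloc[i]!r}: {exc}") from exc

    wide = wide.assign(
        _order=np.arange(len(wide)),
        _age_exit=attained,
        _year_exit=exit_year,
        _death_stratum=death_stratum,
    )
    pieces = []
    for rank, stratum in enumerate(strata):
        piece = wide.copy()
        piece["stratum"] = stratum
        piece["_rank"] = rank
        pieces.append(piece)
    long = pd.concat(pieces, ignore_index=True)
    long = long.sort_values(["_order", "_rank"], kind="stable", ignore_index=True)
    long["c"] = (long["stratum"] != reference).astype(int)
    long["d"] = (long["_death_stratum"] == long["stratum"]).astype(int)

    rates = table.to_frame().rename(
        columns={"age": "_age_exit", "year": "_year_exit", "cause": "stratum",
                 "rate": "expected_rate"}
    )
    long = long.merge(rates, on=["_age_exit", "sex", "_year_exit", "stratum"],
                      how="left", sort=False)
    if long["expected_rate"].isna().any():
        bad = long.loc[long["expected_rate"].isna()].iloc[0]
        raise KeyError(
            f"subject {bad['id']!r}: no life-table cell for age={bad['_age_exit']} "
            f"sex={bad['sex']} year={bad['_year_exit']} cause={bad['stratum']}"
        )
    front = ["id", "stratum", "c", "d", "time", "entry", "expected_rate",
             "age_dx", "sex", "year_dx"]
    rest = [c for c in long.columns
            if c not in front and not c.startswith("_") and c != "cause_code"]
    return long[front + rest + ["cause_code"]]


def truncate_reporting(times, min_time: float = 0.25):
    """Restrict a prediction/reporting grid to ``t >= min_time``.

    Excess-rate estimates immediately after diagnosis mix acute mortality
    with the long-term effects usually of interest, so reporting
    conventionally starts a few months in (default 3 months).  This is
    presentation only — model fitting always uses the full follow-up.
    """

    if min_time < 0:
        raise ValueError("min_time must be >= 0")
    times = np.asarray(times, dtype=float)
    out = times[times >= min_time]
    if out.size == 0 and times.size > 0:
        warnings.warn(
            f"all {times.size} grid points fall before min_time={min_time}; "
            "empty reporting grid",
            stacklevel=2,
        )
    return out
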