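"""Cause-stratified expected-mortality life tables.

Relative-survival methods treat the background (expected) mortality of a
comparable disease-free population as known, read off period life tables
indexed by attained age, sex and calendar year.  Partitioning excess
mortality into components additionally requires the life table itself to be
stratified by mutually exclusive cause groups (e.g. cardiovascular vs. all
remaining causes), so that each component of the excess hazard is matched
with its own expected rate.

This module builds such tables from raw death/population counts, classifies
ICD cause-of-death codes into strata across ICD revisions, and serves rate
lookups with the attained-age convention used throughout the package:
attained age = age at diagnosis + elapsed follow-up, floored to whole years
and capped at the table's maximum age; calendar year advances the same way.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LifeTable",
    "CauseScheme",
    "SWEDISH_CVD_SCHEME",
    "cause_specific_rates",
    "classify_cause",
    "build_from_counts",
]


def _actuarial_rate(d: float, n: float) -> float:
    # -ln(1 - q) with q = d / (N - d/2): converts an interval death
    # probability (deaths over mid-interval population at risk) to a rate
    # per person-year for 1-year cells.
    denom = n - d / 2.0
    if denom <= 0:
        raise ValueError(f"population at risk {n} too small for {d} deaths")
    q = d / denom
    if q >= 1.0:
        raise ValueError(f"death probability {q} >= 1 (d={d}, N={n})")
    return float(-np.log1p(-q))


def cause_specific_rates(d_cause: float, d_total: float, n: float) -> tuple[float, float]:
    """Per-person-year rates for one cause stratum and for the remainder.

    ``rate_cause = -ln(1 - d_cause / (N - d_cause/2))`` and the analogous
    expression with ``d_total - d_cause`` for the residual stratum.  Both
    use the actuarial mid-interval correction of the population at risk.
    """

    if d_cause < 0 or d_total < 0 or n <= 0:
        raise ValueError("counts must be non-negative and N > 0")
    if d_cause > d_total:
        raise ValueError(f"cause deaths {d_cause} exceed total deaths {d_total}")
    if d_total > n:
        raise ValueError(f"total deaths {d_total} exceed population {n}")
    rate_cause = _actuarial_rate(d_cause, n)
    rate_rest = _actuarial_rate(d_total - d_cause, n)
    return rate_cause, rate_rest


# ---------------------------------------------------------------------------
# ICD cause classification


def _parse_icd(code: str) -> tuple[str, int]:
    """Split an ICD code into (letter prefix, 3-digit category).

    Numeric revisions (ICD-7/8/9) give ('', 410) for '410', '410.9' or
    '4109'; ICD-10 gives ('I', 21) for 'I21', 'I21.9' or 'I219'.  Only the
    category block matters for range classification.
    """

    code = code.strip().upper()
    if not code:
        raise ValueError("empty ICD code")
    prefix = ""
    body = code
    if code[0].isalpha():
        prefix, body = code[0], code[1:]
    try:
        num = float(body)
    except ValueError as exc:
        raise ValueError(f"unparseable ICD code {code!r}") from exc
    if prefix:
        # ICD-10 categories are 2 digits after the letter
        cat = int(num) if num < 100 else int(num // 10)
    else:
        # earlier revisions use 3-digit categories ('4109' = 410.9)
        cat = int(num) if num < 1000 else int(num // 10)
    return prefix, cat


@dataclass(frozen=True)
class CauseScheme:
    """Maps ICD codes to a named stratum, by revision validity years.

    ``ranges`` is a sequence of (first_year, last_year, low_code, high_code)
    entries; a death year selects the revision whose validity window
    contains it, and a code falls in the stratum when it lies inside the
    (inclusive) code range.  Everything else goes to ``residual``.
    """

    stratum: str
    ranges: tuple[tuple[int, int, str, str], ...]
    residual: str = "other"

    @property
    def strata(self) -> tuple[str, str]:
        return (self.stratum, self.residual)

    def classify(self, icd_code: str, death_year: int) -> str:
        return classify_cause(icd_code, death_year, self)


#: Circulatory-disease code ranges used by Swedish cause-of-death statistics
#: across ICD revisions 7-10.
SWEDISH_CVD_SCHEME = CauseScheme(
    stratum="cvd",
    ranges=(
        (1961, 1968, "400", "468"),  # ICD-7
        (1969, 1986, "390", "458"),  # ICD-8
        (1987, 1996, "390", "459"),  # ICD-9
        (1997, 2007, "I00", "I99"),  # ICD-10
    ),
)


def classify_cause(icd_code: str, death_year: int, scheme: CauseScheme) -> str:
    """Assign an ICD code to the scheme's stratum or its residual.

    The death year picks the ICD revision; a code inside the revision's
    range (inclusive, whole blocks: 'I219' falls in I00-I99) returns the
    stratum label, anything else the residual label.
    """

    matches = [r for r in scheme.ranges if r[0] <= death_year <= r[1]]
    if not matches:
        years = ", ".join(f"{r[0]}-{r[1]}" for r in scheme.ranges)
        raise ValueError(
            f"death year {death_year} outside the scheme's ICD revision "
            f"windows ({years})"
        )
    prefix, cat = _parse_icd(icd_code)
    for _, _, low, high in matches:
        lo_pre, lo_cat = _parse_icd(low)
        hi_pre, hi_cat = _parse_icd(high)
        if prefix == lo_pre == hi_pre and lo_cat <= cat <= hi_cat:
            return scheme.stratum
    return scheme.residual


# ---------------------------------------------------------------------------
# The life table itself


class LifeTable:
    """Expected mortality rates per person-year by (age, sex, year, cause).

    Backed by a tidy DataFrame with columns ``age, sex, year, cause, rate``;
    one row per cell.  Every (age, sex, year) cell must carry the identical,
    mutually exclusive set of cause strata.
    """

    COLUMNS = ("age", "sex", "year", "cause", "rate")

    def __init__(self, cells: pd.DataFrame):
        df = cells.copy()
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"life table missing columns: {sorted(missing)}")
        df["age"] = df["age"].astype(int)
        df["year"] = df["year"].astype(int)
        df["sex"] = df["sex"].astype(str)
        df["cause"] = df["cause"].astype(str)
        df["rate"] = df["rate"].astype(float)
        if not np.all(np.isfinite(df["rate"])) or (df["rate"] < 0).any():
            bad = df.loc[~np.isfinite(df["rate"]) | (df["rate"] < 0)].iloc[0]
            raise ValueError(
                f"invalid rate {bad['rate']} at age={bad['age']} "
                f"sex={bad['sex']} year={bad['year']} cause={bad['cause']}"
            )
        if df.duplicated(["age", "sex", "year", "cause"]).any():
            raise ValueError("duplicate (age, sex, year, cause) cells")
        per_cell = df.groupby(["age", "sex", "year"])["cause"].nunique()
        if per_cell.nunique() > 1:
            raise ValueError("cause strata differ across (age, sex, year) cells")
        self._df = df[list(self.COLUMNS)].sort_values(
            ["sex", "cause", "year", "age"], kind="stable", ignore_index=True
        )
        self._index = {
            (int(a), s, int(y), c): float(r)
            for a, s, y, c, r in df[list(self.COLUMNS)].itertuples(index=False)
        }
        self.max_age = int(df["age"].max())
        self.causes = tuple(sorted(df["cause"].unique()))

    def to_frame(self) -> pd.DataFrame:
        return self._df.copy()

    def lookup(self, attained_age: float, sex: str, year: int, cause: str) -> float:
        """Rate of the cell containing (floor(attained_age) capped, sex, year).

        Ages above the table maximum are capped there (life tables for a
        national population typically stop at 99).  A missing cell raises —
        expected rates are assumed known, never imputed.
        """

        if cause not in self.causes:
            raise KeyError(
                f"cause {cause!r} not in life table strata {self.causes}"
            )
        age = min(int(np.floor(attained_age)), self.max_age)
        key = (age, str(sex), int(year), cause)
        try:
            return self._index[key]
        except KeyError:
            raise KeyError(
                f"no life-table cell for age={age} sex={sex} year={year} "
                f"cause={cause}"
            ) from None

    def lookup_many(self, attained_age, sex, year, cause) -> np.ndarray:
        """Vectorized :meth:`lookup` over aligned arrays."""

        age = np.minimum(np.floor(np.asarray(attained_age, float)).astype(int), self.max_age)
        sex = np.broadcast_to(np.asarray(sex, dtype=object), age.shape)
        year = np.broadcast_to(np.asarray(year, int), age.shape)
        cause = np.broadcast_to(np.asarray(cause, dtype=object), age.shape)
        out = np.empty(age.shape, dtype=float)
        for i in np.ndindex(age.shape):
            out[i] = self.lookup(age[i], sex[i], year[i], cause[i])
        return out


def build_from_counts(counts: pd.DataFrame, cause_label: str = "cvd",
                      residual_label: str = "other") -> LifeTable:
    """Build a two-stratum life table from raw count data.

    ``counts`` columns: ``age, sex, year, d_cause, d_total, N``.  Each row
    yields two cells via :func:`cause_specific_rates`.
    """

    needed = {"age", "sex", "year", "d_cause", "d_total", "N"}
    missing = needed - set(counts.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    rows = []
    for rec in counts.itertuples(index=False):
        try:
            rc, rr = cause_specific_rates(rec.d_cause, rec.d_total, rec.N)
        except ValueError as exc:
            raise ValueError(
                f"invalid counts at age={rec.age} sex={rec.sex} "
                f"year={rec.year}: {exc}"
            ) from exc
        rows.append((rec.age, rec.sex, rec.year, cause_label, rc))
        rows.append((rec.age, rec.sex, rec.year, residual_label, rr))
    return LifeTable(pd.DataFrame(rows, columns=list(LifeTable.COLUMNS)))
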