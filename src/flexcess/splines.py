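"""Restricted (natural) cubic splines in the truncated-power parameterization.

These splines represent the log cumulative baseline excess hazard as a
function of log time, and optionally continuous covariates (age at
diagnosis, calendar year).  A basis with ``df`` degrees of freedom is built
from ``df + 1`` knots: the first column is the identity (linear) term and
each interior knot contributes one restricted cubic column

    v_j(x) = (x - k_j)_+^3 - a_j (x - k_min)_+^3 - (1 - a_j) (x - k_max)_+^3

with ``a_j = (k_max - k_j) / (k_max - k_min)``.  The two constraints
absorbed into ``v_j`` make every column (and hence any linear combination)
exactly linear beyond the boundary knots and C2-continuous everywhere.

The columns are deliberately NOT orthogonalized: fitted spline coefficients
are therefore basis-dependent, but every model prediction (which only sees
the spanned function space) is invariant to that choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["KnotVector", "SplineBasis", "place_knots", "rcs_eval", "rcs_deriv"]


@dataclass(frozen=True)
class KnotVector:
    """Strictly increasing knot positions on the evaluation scale.

    Degrees of freedom (number of basis columns) = ``len(values) - 1``.
    """

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        if len(vals) < 2:
            raise ValueError("a knot vector needs at least 2 knots")
        if any(not np.isfinite(v) for v in vals):
            raise ValueError("knots must be finite")
        diffs = np.diff(vals)
        if np.any(diffs <= 0):
            i = int(np.argmax(diffs <= 0))
            raise ValueError(
                f"knots must be strictly increasing; knots[{i}]={vals[i]} >= "
                f"knots[{i + 1}]={vals[i + 1]}"
            )
        object.__setattr__(self, "values", vals)

    @property
    def df(self) -> int:
        return len(self.values) - 1

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self):
        return iter(self.values)


@dataclass(frozen=True)
class SplineBasis:
    """A restricted cubic spline basis bound to a knot vector.

    ``scale`` records whether the basis lives on log time or on a covariate
    axis; it is informational only — evaluation is identical.
    """

    knots: KnotVector
    scale: str = "log_time"

    def __post_init__(self) -> None:
        if self.scale not in ("log_time", "covariate"):
            raise ValueError(f"unknown scale {self.scale!r}")

    @property
    def df(self) -> int:
        return self.knots.df

    def eval(self, x) -> np.ndarray:
        return rcs_eval(self, x)

    def deriv(self, x) -> np.ndarray:
        return rcs_deriv(self, x)


def place_knots(values, df: int, centile_scheme=None) -> KnotVector:
    """Place knots at centiles of ``values``.

    By default the ``df + 1`` knots sit at equally spaced centiles from the
    0th to the 100th (so df=5 gives 0/20/40/60/80/100, df=3 gives
    0/33.33/66.67/100).  For the log-time scale the caller must pass the
    *uncensored* event times, already log-transformed.  A covariate scheme
    such as (5, 25, 50, 75, 95) may be supplied explicitly.

    Raises if two requested centiles land on the same value: silently
    merging knots would change the degrees of freedom under the caller's
    feet.
    """

    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("cannot place knots on an empty value set")
    if not np.all(np.isfinite(vals)):
        raise ValueError("values for knot placement must be finite")
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    if centile_scheme is None:
        centiles = np.linspace(0.0, 100.0, df + 1)
    else:
        centiles = np.asarray(centile_scheme, dtype=float)
        if centiles.size != df + 1:
            raise ValueError(
                f"centile scheme has {centiles.size} entries but df={df} "
                f"needs {df + 1} knots"
            )
    knots = np.percentile(vals, centiles)
    dup = np.flatnonzero(np.diff(knots) <= 0)
    if dup.size:
        i = int(dup[0])
        raise ValueError(
            f"centiles {centiles[i]:g} and {centiles[i + 1]:g} both give knot "
            f"value {knots[i]:g}; too few distinct values for df={df}"
        )
    return KnotVector(tuple(knots))


def _as_basis(basis) -> KnotVector:
    if isinstance(basis, SplineBasis):
        return basis.knots
    if isinstance(basis, KnotVector):
        return basis
    return KnotVector(tuple(basis))


def rcs_eval(basis, x) -> np.ndarray:
    """Evaluate the basis at ``x``: shape (..., df).

    Column 0 is ``x`` itself; restricted cubic columns vanish for
    ``x <= k_min`` and every column is linear in ``x`` for ``x >= k_max``.
    Extrapolation beyond the boundary knots is linear by construction.
    """

    knots = np.asarray(_as_basis(basis).values)
    x = np.asarray(x, dtype=float)
    kmin, kmax = knots[0], knots[-1]
    span = kmax - kmin
    out = np.empty(x.shape + (len(knots) - 1,), dtype=float)
    out[..., 0] = x
    for j, kj in enumerate(knots[1:-1], start=1):
        aj = (kmax - kj) / span
        out[..., j] = (
            np.clip(x - kj, 0.0, None) ** 3
            - aj * np.clip(x - kmin, 0.0, None) ** 3
            - (1.0 - aj) * np.clip(x - kmax, 0.0, None) ** 3
        )
    return out


def rcs_deriv(basis, x) -> np.ndarray:
    """Analytic derivative d/dx of each basis column: shape (..., df).

    Column 0 differentiates to 1 everywhere; below the first knot all
    remaining columns have derivative 0 (constant-slope region).
    """

    knots = np.asarray(_as_basis(basis).values)
    x = np.asarray(x, dtype=float)
    kmin, kmax = knots[0], knots[-1]
    span = kmax - kmin
    out = np.empty(x.shape + (len(knots) - 1,), dtype=float)
    out[..., 0] = 1.0
    for j, kj in enumerate(knots[1:-1], start=1):
        aj = (kmax - kj) / span
        out[..., j] = 3.0 * (
            np.clip(x - kj, 0.0, None) ** 2
            - aj * np.clip(x - kmin, 0.0, None) ** 2
            - (1.0 - aj) * np.clip(x - kmax, 0.0, None) ** 2
        )
    return out
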