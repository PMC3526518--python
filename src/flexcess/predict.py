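"""Post-estimation predictions from partitioned excess-hazard models.

Component-specific excess mortality rates, relative survival, and crude
probabilities of death in the presence of competing causes:

    Cr_j(t)      = ∫₀ᵗ S*(u) R(u) λ_j(u) du     (excess component j)
    Cr_other(t)  = ∫₀ᵗ S*(u) R(u) h*(u) du       (background causes)

with R(u) = Π_j R_j(u) = exp(−Σ_j Θ_j(u)) and S*(u) the expected survival
from the cause-summed life-table rates.  The integrals are evaluated by
the trapezoidal rule on a uniform grid of ``n`` sub-intervals; because the
integrands involve splines of ln u the grid starts at a small ``t_min``
(one day) and the remaining [0, t_min] sliver is added as a single
rectangle — its contribution is bounded by t_min · max integrand.

Confidence intervals use the delta method: the gradient of each (log-)
functional with respect to θ̂ by central finite differences, variance
gᵀVg, interval formed on the log scale and back-transformed so rates and
probabilities stay positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .lifetables import LifeTable
from .model import FittedModel

__all__ = [
    "relative_survival",
    "excess_rate",
    "crude_probabilities",
    "delta_method_ci",
    "conditional_cause_shares",
    "CrudeProbabilityCurve",
    "expected_rate_trajectory",
]

T_MIN = 1.0 / 365.24


def relative_survival(model: FittedModel, profile: dict, t, strata_nonref=(False, True)):
    """Per-stratum relative survival R_j = exp(−Θ_j) and their product.

    ``strata_nonref`` lists the stratum indicators to evaluate (default the
    two-stratum case: reference then non-reference).  Returns (R_total,
    list of R_j) aligned with that list.
    """

    t = np.asarray(t, dtype=float)
    per = [np.exp(-model.cumulative_excess(profile, flag, t)) for flag in strata_nonref]
    total = np.prod(np.stack(per, axis=0), axis=0)
    return total, per


def expected_rate_trajectory(
    table: LifeTable, age_dx: float, sex: str, year_dx: int, u, cause: str
) -> np.ndarray:
    """h*_cause(u) along follow-up, advancing attained age and calendar year.

    Stepwise constant within 1-year life-table cells, matching the period
    format of the table.
    """

    u = np.asarray(u, dtype=float)
    age = age_dx + u
    year = (year_dx + np.floor(u)).astype(int)
    return table.lookup_many(age, sex, year, cause)


@dataclass
class CrudeProbabilityCurve:
    """Crude probabilities of death along a reporting grid.

    ``crude[s]`` is the probability of having died of excess cause ``s``
    by each time; ``crude_other`` of background (non-excess) causes;
    ``surv`` the all-cause survival S*(t)R(t).  ``ci`` maps stratum labels
    plus ``"background"`` and ``"surv"`` to (lower, upper) arrays when
    intervals were requested.
    """

    times: np.ndarray
    crude: dict
    crude_other: np.ndarray
    surv: np.ndarray
    ci: dict | None = None

    @property
    def crude_total(self) -> np.ndarray:
        """Σ_j Cr_j(t): the all-excess-cause (net-disease) crude probability."""

        return np.sum(np.stack(list(self.crude.values()), axis=0), axis=0)


def _curve_point_estimates(model, table, profile, age_dx, sex, year_dx,
                           strata, reference, times, n, t_min, theta=None,
                           warn_negative=True):
    T = float(np.max(times))
    grid = np.linspace(t_min, T, n + 1)
    hstar = {s: expected_rate_trajectory(table, age_dx, sex, year_dx, grid, s)
             for s in strata}
    hstar_sum = np.sum(np.stack(list(hstar.values()), axis=0), axis=0)
    Theta = {}
    lam = {}
    for s in strata:
        nonref = s != reference
        Theta[s] = model.cumulative_excess(profile, nonref, grid, theta)
        lam[s] = model.excess_hazard(profile, nonref, grid, theta)
        if warn_negative and np.any(lam[s] < 0):
            warnings.warn(
                f"negative excess hazard for stratum {s!r} on part of the grid; "
                "its crude probability may locally decrease",
                stacklevel=3,
            )
    # expected survival from the cause-summed rates, integrated on the same
    # grid (plus the [0, t_min] rectangle) so the accounting identity holds
    # to quadrature accuracy
    Hstar = _cumtrapz(hstar_sum, grid) + t_min * hstar_sum[0]
    Sstar = np.exp(-Hstar)
    R = np.exp(-np.sum(np.stack([Theta[s] for s in strata], axis=0), axis=0))
    SR = Sstar * R
    crude = {}
    for s in strata:
        f = SR * lam[s]
        # [0, t_min] sliver: ∫₀^{t_min} λ_j = Θ_j(t_min) exactly — robust
        # even when λ_j diverges as t → 0 — damped by S*R at t_min
        crude[s] = np.interp(times, grid, _cumtrapz(f, grid) + Theta[s][0] * SR[0])
    f_other = SR * hstar_sum
    crude_other = np.interp(times, grid, _cumtrapz(f_other, grid) + t_min * f_other[0])
    surv = np.interp(times, grid, SR)
    return crude, crude_other, surv


def _cumtrapz(y, x):
    out = np.empty_like(y)
    out[0] = 0.0
    np.cumsum(0.5 * (y[1:] + y[:-1]) * np.diff(x), out=out[1:])
    return out


def crude_probabilities(
    model: FittedModel,
    table: LifeTable,
    profile: dict,
    age_dx: float,
    sex: str,
    year_dx: int,
    strata,
    times,
    n: int = 1000,
    t_min: float = T_MIN,
    reference: str | None = None,
    ci: bool = True,
    level: float = 0.95,
) -> CrudeProbabilityCurve:
    """Crude probabilities of death for every excess component and for
    background causes, by trapezoidal integration on ``n`` sub-intervals.

    ``strata`` are the life-table cause labels; ``reference`` (default:
    the model's stored reference, else the first stratum) marks which one
    the model treats as the c=0 stratum.  Marginality — the sum of the
    component curves equalling the curve from the summed excess hazard —
    holds by construction of the integration.
    """

    times = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if times[0] < t_min:
        raise ValueError(f"times must start at or after t_min={t_min:.5f}")
    if n < 100:
        raise ValueError("n >= 100 sub-intervals required")
    strata = list(strata)
    if reference is None:
        reference = model.reference if model.reference in strata else strata[0]

    crude, crude_other, surv = _curve_point_estimates(
        model, table, profile, age_dx, sex, year_dx, strata, reference,
        times, n, t_min)
    cis = None
    if ci:
        V = model.vcov.to_numpy()
        keys = strata + ["background", "surv"]

        def functional(theta):
            c, co, sv = _curve_point_estimates(
                model, table, profile, age_dx, sex, year_dx, strata, reference,
                times, n, t_min, theta=theta, warn_negative=False)
            return np.concatenate([c[s] for s in strata] + [co, sv])

        est = np.concatenate([crude[s] for s in strata] + [crude_other, surv])
        lo, hi = _delta_log_ci(functional, model.theta, V, est, level)
        m = len(times)
        cis = {}
        for i, k in enumerate(keys):
            cis[k] = (lo[i * m:(i + 1) * m], hi[i * m:(i + 1) * m])
    return CrudeProbabilityCurve(times=times, crude=crude,
                                 crude_other=crude_other, surv=surv, ci=cis)


def _delta_log_ci(functional, theta, V, est, level):
    """CI via FD gradient of ln f(θ); floors keep the log finite."""

    eps = np.finfo(float).eps
    est_f = np.maximum(np.abs(est), eps)
    p = theta.size
    G = np.empty((est.size, p))
    for k in range(p):
        h = 1e-5 * (1.0 + abs(theta[k]))
        tp, tm = theta.copy(), theta.copy()
        tp[k] += h
        tm[k] -= h
        fp, fm = functional(tp), functional(tm)
        if not (np.all(np.isfinite(fp)) and np.all(np.isfinite(fm))):
            bad = np.flatnonzero(~(np.isfinite(fp) & np.isfinite(fm)))[0]
            raise FloatingPointError(
                f"non-finite delta-method gradient at output index {bad}"
            )
        G[:, k] = (np.log(np.maximum(np.abs(fp), eps))
                   - np.log(np.maximum(np.abs(fm), eps))) / (2 * h)
    var = np.einsum("ij,jk,ik->i", G, V, G)
    se = np.sqrt(np.maximum(var, 0.0))
    z = stats.norm.ppf(0.5 + level / 2.0)
    return est_f * np.exp(-z * se), est_f * np.exp(z * se)


def delta_method_ci(model: FittedModel, functional, level: float = 0.95,
                    transform: str = "log"):
    """Generic delta-method interval for a positive functional of θ̂.

    ``functional(theta) -> array``; gradients by central finite differences
    with step 1e-5·(1+|θ_k|).  ``transform="log"`` forms the interval on
    the log scale (rates, probabilities); ``"identity"`` gives the plain
    Wald interval, exact when the functional is linear in θ.
    """

    theta = model.theta
    V = model.vcov.to_numpy()
    est = np.atleast_1d(np.asarray(functional(theta), dtype=float))
    if transform == "log":
        lo, hi = _delta_log_ci(lambda th: np.atleast_1d(functional(th)),
                               theta, V, est, level)
        return est, lo, hi
    if transform != "identity":
        raise ValueError(f"unknown transform {transform!r}")
    p = theta.size
    G = np.empty((est.size, p))
    for k in range(p):
        h = 1e-5 * (1.0 + abs(theta[k]))
        tp, tm = theta.copy(), theta.copy()
        tp[k] += h
        tm[k] -= h
        fp = np.atleast_1d(functional(tp))
        fm = np.atleast_1d(functional(tm))
        if not (np.all(np.isfinite(fp)) and np.all(np.isfinite(fm))):
            raise FloatingPointError("non-finite delta-method gradient")
        G[:, k] = (fp - fm) / (2 * h)
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", G, V, G), 0.0))
    z = stats.norm.ppf(0.5 + level / 2.0)
    return est, est - z * se, est + z * se


def excess_rate(model: FittedModel, profile: dict, stratum_nonref: bool, times,
                level: float = 0.95, per: float = 1000.0):
    """Component excess mortality rate λ_j(t) with log-scale delta CI.

    ``per`` rescales to events per ``per`` person-years (default 1000,
    the usual reporting unit).
    """

    times = np.atleast_1d(np.asarray(times, dtype=float))
    est, lo, hi = delta_method_ci(
        model,
        lambda th: model.excess_hazard(profile, stratum_nonref, times, th),
        level=level, transform="log",
    )
    return per * est, per * lo, per * hi


def conditional_cause_shares(curve: CrudeProbabilityCurve, t: float) -> dict:
    """Share of deaths by time ``t`` attributed to each cause.

    Conditioning on death by ``t``: share_j = Cr_j(t) / (1 − S(t)), with
    background (non-excess) causes under the key ``"background"`` so a
    stratum labelled "other" cannot collide; shares sum to 1.
    """

    idx = int(np.argmin(np.abs(curve.times - t)))
    if not np.isclose(curve.times[idx], t):
        raise ValueError(f"t={t} is not on the curve's time grid")
    if 1.0 - curve.surv[idx] <= 1e-12:
        raise ValueError(f"no deaths by t={t}; shares undefined")
    # the denominator 1 - S(t) is taken as the sum of the component curves,
    # which it equals up to quadrature error, so shares sum to exactly 1
    total_death = float(sum(c[idx] for c in curve.crude.values()) + curve.crude_other[idx])
    shares = {s: float(c[idx] / total_death) for s, c in curve.crude.items()}
    shares["background"] = float(curve.crude_other[idx] / total_death)
    return shares
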