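"""Flexible parametric excess-hazard models on the log cumulative scale.

The log cumulative excess hazard for cause stratum ``j`` is modelled as

    ln Θ_j(t; x) = s(ln t; γ0, k0) + xᵀβ
                   + c_j [ β_c + s(ln t; γ_c, k_c) + xᵀβ_c ]
                   + Σ_i s(ln t; γ_i, k_i) x_i

where ``s`` are restricted cubic splines of log time, ``c_j`` indicates a
non-reference stratum, shared effects ``β`` act on every stratum, the
bracketed terms let the non-reference stratum's baseline and covariate
effects deviate freely, and the final sum holds ordinary time-dependent
(non-proportional) covariate effects.  Setting the stratum terms aside
recovers the single-outcome model for all-cause excess mortality.

Each long-format row contributes ``d ln(h* + λ(t)) − Θ(t)`` to the
log likelihood, with ``h*`` the row's expected (background) rate at exit
and ``λ = dΘ/dt`` the excess hazard; expected cumulative hazards are
parameter-free and dropped.  The excess hazard may legitimately be
negative, but the total hazard ``h* + λ`` must be positive at event times;
below a small floor the log is continued linearly so the optimizer is
pushed back into the valid region rather than crashing.

Fitting is Newton-type with backtracking line search (observed information
from finite differences of the analytic score) with a quasi-Newton
fallback; the covariance matrix is the inverse observed information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .splines import KnotVector, place_knots, rcs_deriv, rcs_eval

__all__ = [
    "ModelSpec",
    "FittedModel",
    "fit",
    "log_likelihood",
    "linear_predictor",
    "cumulative_excess",
    "excess_hazard",
    "emrr",
    "lr_test",
    "information_criteria",
]

_LOG_FLOOR = 1e-12


# ---------------------------------------------------------------------------
# Specification


@dataclass(frozen=True)
class ModelSpec:
    """Model structure, before knots are resolved against a data set.

    ``shared`` covariates act identically on every stratum; each name in
    ``cause_specific`` gets an extra interaction with the non-reference
    stratum indicator.  ``cause_df``/``cause_knots`` give the deviation
    spline that lets the non-reference baseline vary freely; ``tvc`` maps a
    covariate name to the df (or explicit knots) of its time-dependent
    effect.  A covariate name may be a product ``"a*b"`` of two columns —
    the restricted (linear-component-only) way to include higher-order
    interactions.
    """

    baseline_df: int = 5
    baseline_knots: KnotVector | None = None
    shared: tuple[str, ...] = ()
    cause_specific: tuple[str, ...] = ()
    cause_shift: bool = True
    cause_df: int | None = None
    cause_knots: KnotVector | None = None
    tvc: tuple[tuple[str, object], ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "shared", tuple(self.shared))
        object.__setattr__(self, "cause_specific", tuple(self.cause_specific))
        tvc = self.tvc.items() if isinstance(self.tvc, dict) else self.tvc
        object.__setattr__(self, "tvc", tuple((str(k), v) for k, v in tvc))


@dataclass(frozen=True)
class ResolvedKnots:
    baseline: KnotVector
    cause: KnotVector | None
    tvc: tuple[tuple[str, KnotVector], ...]

    def tvc_knots(self, name: str) -> KnotVector:
        return dict(self.tvc)[name]


@dataclass(frozen=True)
class DataSummary:
    """Enough about the fitted data to verify two fits used the same set."""

    n_subjects: int
    n_rows: int
    strata: tuple[str, ...]
    events: tuple[tuple[str, int], ...]
    person_time: float

    def __eq__(self, other):
        if not isinstance(other, DataSummary):
            return NotImplemented
        return (
            self.n_subjects == other.n_subjects
            and self.n_rows == other.n_rows
            and self.strata == other.strata
            and self.events == other.events
            and np.isclose(self.person_time, other.person_time, rtol=1e-12)
        )


def _column(data, name: str) -> np.ndarray:
    """Fetch a covariate column; ``"a*b"`` materializes the product."""

    if name in data:
        return np.asarray(data[name], dtype=float)
    if "*" in name:
        parts = name.split("*")
        out = np.ones_like(np.asarray(data[parts[0].strip()], dtype=float))
        for p in parts:
            out = out * np.asarray(data[p.strip()], dtype=float)
        return out
    raise KeyError(f"covariate {name!r} not found in data")


def resolve_knots(spec: ModelSpec, long_data: pd.DataFrame) -> ResolvedKnots:
    """Place every knot vector on the uncensored log event times."""

    death_t = long_data.loc[long_data["d"] == 1, "time"].to_numpy(float)
    if death_t.size == 0:
        raise ValueError("no events in data; cannot place knots")
    log_t = np.log(death_t)
    baseline = spec.baseline_knots or place_knots(log_t, spec.baseline_df)
    cause = None
    if spec.cause_knots is not None:
        cause = spec.cause_knots
    elif spec.cause_df is not None:
        cause = place_knots(log_t, spec.cause_df)
    tvc = []
    for name, df_or_knots in spec.tvc:
        if isinstance(df_or_knots, KnotVector):
            tvc.append((name, df_or_knots))
        else:
            tvc.append((name, place_knots(log_t, int(df_or_knots))))
    return ResolvedKnots(baseline=baseline, cause=cause, tvc=tuple(tvc))


def _design(spec: ModelSpec, knots: ResolvedKnots, data, ln_t, c,
            nonref_present: bool) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Design matrix X and its d/d(ln t) companion Xd for long rows.

    ``data`` is a mapping of column name -> array aligned with ``ln_t`` and
    ``c`` (the non-reference stratum indicator).  θ enters the model only
    through η = Xθ, so λ and all derivatives follow from (X, Xd).
    """

    ln_t = np.asarray(ln_t, dtype=float)
    c = np.asarray(c, dtype=float)
    ones = np.ones_like(ln_t)
    zeros = np.zeros_like(ln_t)
    cols, dcols, names = [], [], []

    def add(name, col, dcol):
        names.append(name)
        cols.append(np.broadcast_to(col, ln_t.shape))
        dcols.append(np.broadcast_to(dcol, ln_t.shape))

    add("cons", ones, zeros)
    B, Bd = rcs_eval(knots.baseline, ln_t), rcs_deriv(knots.baseline, ln_t)
    for i in range(B.shape[-1]):
        add(f"rcs{i + 1}", B[..., i], Bd[..., i])
    for name in spec.shared:
        add(name, _column(data, name), zeros)
    if nonref_present:
        if spec.cause_shift:
            add("c", c, zeros)
        if knots.cause is not None:
            Bc, Bcd = rcs_eval(knots.cause, ln_t), rcs_deriv(knots.cause, ln_t)
            for i in range(Bc.shape[-1]):
                add(f"c#rcs{i + 1}", c * Bc[..., i], c * Bcd[..., i])
        for name in spec.cause_specific:
            add(f"c#{name}", c * _column(data, name), zeros)
    for name, kv in knots.tvc:
        x = _column(data, name)
        Bt, Btd = rcs_eval(kv, ln_t), rcs_deriv(kv, ln_t)
        for i in range(Bt.shape[-1]):
            add(f"{name}#rcs{i + 1}", x * Bt[..., i], x * Btd[..., i])
    X = np.stack(cols, axis=-1)
    Xd = np.stack(dcols, axis=-1)
    return X, Xd, names


# ---------------------------------------------------------------------------
# Likelihood


class _Likelihood:
    """Vectorized log likelihood, score, and FD observed information."""

    def __init__(self, spec: ModelSpec, knots: ResolvedKnots, long_data: pd.DataFrame):
        t = long_data["time"].to_numpy(float)
        if np.any(t <= 0):
            raise ValueError("all survival times must be > 0")
        c = long_data["c"].to_numpy(float) if "c" in long_data else np.zeros(len(long_data))
        nonref = bool(np.any(c > 0))
        data = {k: long_data[k].to_numpy() for k in long_data.columns
                if long_data[k].dtype.kind in "ifb"}
        self.X, self.Xd, self.names = _design(spec, knots, data, np.log(t), c, nonref)
        self.t = t
        self.d = long_data["d"].to_numpy(float)
        self.hstar = long_data["expected_rate"].to_numpy(float)
        if np.any(self.hstar < 0) or not np.all(np.isfinite(self.hstar)):
            raise ValueError("expected rates must be finite and >= 0")
        self.n_params = self.X.shape[1]
        entry = long_data["entry"].to_numpy(float) if "entry" in long_data else np.zeros_like(t)
        self.has_entry = bool(np.any(entry > 0))
        if self.has_entry:
            idx = np.flatnonzero(entry > 0)
            Xe, _, _ = _design(spec, knots, {k: v[idx] for k, v in data.items()},
                               np.log(entry[idx]), c[idx], nonref)
            self.X_entry = Xe
        # data summary for LR-test nesting checks (subject count from ids)
        n_sub = long_data["id"].nunique() if "id" in long_data else len(long_data)
        strata = (tuple(sorted(long_data["stratum"].unique()))
                  if "stratum" in long_data else ("all",))
        ev = []
        for s in strata:
            mask = (long_data["stratum"] == s) if "stratum" in long_data else slice(None)
            ev.append((s, int(long_data.loc[mask, "d"].sum()) if s != "all"
                       else int(self.d.sum())))
        self.summary = DataSummary(
            n_subjects=int(n_sub), n_rows=len(long_data), strata=strata,
            events=tuple(ev), person_time=float(t.sum()),
        )

    def _parts(self, theta):
        with np.errstate(over="ignore", invalid="ignore"):
            eta = self.X @ theta
            Theta = np.exp(eta)
            u = self.Xd @ theta
            lam = Theta * u / self.t
            mu = self.hstar + lam
        return Theta, u, lam, mu

    def loglik(self, theta) -> float:
        Theta, _, _, mu = self._parts(theta)
        # linear continuation of log below the floor keeps the surface
        # smooth while heavily penalizing non-positive total hazards
        with np.errstate(over="ignore", invalid="ignore"):
            logmu = np.where(mu > _LOG_FLOOR, np.log(np.maximum(mu, _LOG_FLOOR)),
                             np.log(_LOG_FLOOR) + (mu - _LOG_FLOOR) / _LOG_FLOOR)
            ll = float(np.dot(self.d, logmu) - Theta.sum())
            if self.has_entry:
                ll += float(np.exp(self.X_entry @ theta).sum())
        return ll if np.isfinite(ll) else -np.inf

    def score(self, theta) -> np.ndarray:
        Theta, _, lam, mu = self._parts(theta)
        with np.errstate(over="ignore", invalid="ignore"):
            dlog = np.where(mu > _LOG_FLOOR, 1.0 / np.maximum(mu, _LOG_FLOOR),
                            1.0 / _LOG_FLOOR)
            w = self.d * dlog
            g = self.X.T @ (w * lam - Theta) + self.Xd.T @ (w * Theta / self.t)
            if self.has_entry:
                g = g + self.X_entry.T @ np.exp(self.X_entry @ theta)
        return g

    def observed_information(self, theta) -> np.ndarray:
        """-Hessian of the log likelihood by central FD of the score."""

        p = self.n_params
        H = np.empty((p, p))
        for k in range(p):
            h = 1e-6 * (1.0 + abs(theta[k]))
            tp, tm = theta.copy(), theta.copy()
            tp[k] += h
            tm[k] -= h
            H[:, k] = (self.score(tp) - self.score(tm)) / (2 * h)
        H = -(H + H.T) / 2.0
        return H


def log_likelihood(spec: ModelSpec, theta, long_data: pd.DataFrame,
                   knots: ResolvedKnots | None = None) -> float:
    """Σ rows d·ln(h* + λ(t)) − Θ(t), expected cumulative hazards dropped."""

    knots = knots or resolve_knots(spec, long_data)
    return _Likelihood(spec, knots, long_data).loglik(np.asarray(theta, float))


# ---------------------------------------------------------------------------
# Fitted model


@dataclass
class FittedModel:
    """Maximum-likelihood fit of a component-partitioned excess-hazard model."""

    spec: ModelSpec
    knots: ResolvedKnots
    params: pd.Series            # θ̂ indexed by term name
    vcov: pd.DataFrame           # inverse observed information
    loglik: float
    converged: bool
    n_iter: int
    grad_norm: float
    summary: DataSummary
    reference: str | None = None

    @property
    def n_params(self) -> int:
        return len(self.params)

    @property
    def theta(self) -> np.ndarray:
        return self.params.to_numpy()

    # -- prediction plumbing -------------------------------------------------

    def design_row(self, profile: dict, stratum_nonref: bool, t) -> tuple[np.ndarray, np.ndarray]:
        """(X, Xd) rows for a covariate profile at time(s) t."""

        t = np.asarray(t, dtype=float)
        ln_t = np.log(t)
        c = np.full(ln_t.shape, 1.0 if stratum_nonref else 0.0)
        data = {k: np.broadcast_to(np.asarray(v, dtype=float), ln_t.shape)
                for k, v in profile.items()}
        X, Xd, names = _design(self.spec, self.knots, data, ln_t, c,
                               nonref_present="c" in self.params.index
                               or any(n.startswith("c#") for n in self.params.index))
        if names != list(self.params.index):
            raise ValueError(
                f"design mismatch: expected terms {list(self.params.index)}, got {names}"
            )
        return X, Xd

    def linear_predictor(self, profile: dict, stratum_nonref: bool, t,
                         theta=None) -> np.ndarray:
        X, _ = self.design_row(profile, stratum_nonref, t)
        th = self.theta if theta is None else np.asarray(theta, float)
        return X @ th

    def cumulative_excess(self, profile: dict, stratum_nonref: bool, t,
                          theta=None) -> np.ndarray:
        """Θ_j(t) = exp(η)."""

        return np.exp(self.linear_predictor(profile, stratum_nonref, t, theta))

    def excess_hazard(self, profile: dict, stratum_nonref: bool, t,
                      theta=None) -> np.ndarray:
        """λ_j(t) = Θ_j(t) · dη/d(ln t) / t; may be negative."""

        t = np.asarray(t, dtype=float)
        X, Xd = self.design_row(profile, stratum_nonref, t)
        th = self.theta if theta is None else np.asarray(theta, float)
        lam = np.exp(X @ th) * (Xd @ th) / t
        return lam


def linear_predictor(model: FittedModel, profile: dict, stratum_nonref: bool, t):
    return model.linear_predictor(profile, stratum_nonref, t)


def cumulative_excess(model: FittedModel, profile: dict, stratum_nonref: bool, t):
    return model.cumulative_excess(profile, stratum_nonref, t)


def excess_hazard(model: FittedModel, profile: dict, stratum_nonref: bool, t):
    lam = model.excess_hazard(profile, stratum_nonref, t)
    if np.any(np.asarray(lam) < 0):
        warnings.warn("negative fitted excess hazard at some evaluation points",
                      stacklevel=2)
    return lam


def model_from_theta(spec: ModelSpec, knots: ResolvedKnots, theta, names=None,
                     vcov=None, reference=None) -> FittedModel:
    """Assemble a FittedModel from known parameters (no fitting).

    Useful for evaluating predictions under a fully specified model, e.g.
    closed-form checks; the covariance defaults to zero.
    """

    theta = np.asarray(theta, dtype=float)
    if names is None:
        # build names from a dummy design evaluation
        dummy = {nm: np.zeros(1) for nm in _needed_covariates(spec)}
        _, _, names = _design(spec, knots, dummy, np.zeros(1), np.ones(1),
                              nonref_present=spec.cause_shift or knots.cause is not None
                              or bool(spec.cause_specific))
    if len(names) != theta.size:
        raise ValueError(f"theta has {theta.size} entries for {len(names)} terms")
    V = np.zeros((theta.size, theta.size)) if vcov is None else np.asarray(vcov, float)
    params = pd.Series(theta, index=names)
    return FittedModel(
        spec=spec, knots=knots, params=params,
        vcov=pd.DataFrame(V, index=names, columns=names),
        loglik=np.nan, converged=True, n_iter=0, grad_norm=np.nan,
        summary=DataSummary(0, 0, (), (), 0.0), reference=reference,
    )


def _needed_covariates(spec: ModelSpec):
    names = set()
    for nm in list(spec.shared) + list(spec.cause_specific) + [k for k, _ in spec.tvc]:
        for part in nm.split("*"):
            names.add(part.strip())
    return sorted(names)


# ---------------------------------------------------------------------------
# Fitting


def _initial_theta(lik: _Likelihood) -> np.ndarray:
    """Zeros, except a crude exponential excess-rate start for the baseline.

    An exponential excess hazard has ln Θ = ln(rate) + ln t: intercept
    ln(rate) from (events − expected events)/person-time, slope 1 on the
    linear spline column.
    """

    theta = np.zeros(lik.n_params)
    D = lik.d.sum()
    E = float(np.dot(lik.hstar, lik.t))
    PT = float(lik.t.sum())
    rate = max((D - E) / PT, 1e-4)
    theta[lik.names.index("cons")] = np.log(rate)
    theta[lik.names.index("rcs1")] = 1.0
    return theta


def fit(
    spec: ModelSpec,
    long_data: pd.DataFrame,
    init=None,
    max_iter: int = 100,
    tol: float = 1e-9,
    reference: str | None = None,
) -> FittedModel:
    """Maximize the excess-hazard likelihood by Newton iteration.

    Convergence requires the scaled score norm ``max|g| / (1 + |ll|)`` to
    fall below ``tol``.  When the observed information is not positive
    definite the step falls back to a ridged solve, and ultimately to
    quasi-Newton (L-BFGS) restarts; failure to converge is reported
    honestly in the result, never silently.
    """

    knots = resolve_knots(spec, long_data)
    lik = _Likelihood(spec, knots, long_data)
    theta = np.asarray(init, float).copy() if init is not None else _initial_theta(lik)
    if theta.size != lik.n_params:
        raise ValueError(f"init has {theta.size} entries for {lik.n_params} parameters")

    ll = lik.loglik(theta)
    n_iter = 0
    used_fallback = False
    for n_iter in range(1, max_iter + 1):
        g = lik.score(theta)
        scale = 1.0 + abs(ll)
        if np.max(np.abs(g)) / scale < tol:
            break
        H = lik.observed_information(theta)
        step = None
        try:
            cho = linalg.cho_factor(H)
            step = linalg.cho_solve(cho, g)
        except linalg.LinAlgError:
            # ridge the information until it solves
            ridge = 1e-6 * max(1.0, float(np.trace(H)) / lik.n_params)
            for _ in range(12):
                try:
                    cho = linalg.cho_factor(H + ridge * np.eye(lik.n_params))
                    step = linalg.cho_solve(cho, g)
                    break
                except linalg.LinAlgError:
                    ridge *= 10.0
        if step is None or not np.all(np.isfinite(step)):
            used_fallback = True
            break
        # backtracking line search on the log likelihood
        alpha = 1.0
        for _ in range(40):
            cand = theta + alpha * step
            ll_cand = lik.loglik(cand)
            if np.isfinite(ll_cand) and ll_cand > ll - 1e-12 * scale:
                break
            alpha *= 0.5
        else:
            used_fallback = True
            break
        if ll_cand < ll:  # no uphill step found along the Newton direction
            used_fallback = True
            break
        improved = ll_cand - ll
        theta, ll = cand, ll_cand
        if improved < 1e-13 * scale and np.max(np.abs(lik.score(theta))) / scale < 1e2 * tol:
            break

    if used_fallback:
        res = optimize.minimize(
            lambda th: -lik.loglik(th), theta, jac=lambda th: -lik.score(th),
            method="L-BFGS-B", options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10},
        )
        if res.fun < -ll or not np.isfinite(ll):
            theta, ll = res.x, -res.fun
        # polish with a few more Newton steps
        for _ in range(20):
            g = lik.score(theta)
            if np.max(np.abs(g)) / (1.0 + abs(ll)) < tol:
                break
            H = lik.observed_information(theta)
            try:
                step = linalg.cho_solve(linalg.cho_factor(H), g)
            except linalg.LinAlgError:
                break
            alpha, ok = 1.0, False
            for _ in range(40):
                cand = theta + alpha * step
                ll_cand = lik.loglik(cand)
                if np.isfinite(ll_cand) and ll_cand >= ll:
                    ok = True
                    break
                alpha *= 0.5
            if not ok:
                break
            theta, ll = cand, ll_cand

    g = lik.score(theta)
    grad_norm = float(np.max(np.abs(g)))
    converged = grad_norm / (1.0 + abs(ll)) < 100 * tol
    H = lik.observed_information(theta)
    try:
        V = linalg.inv(H)
        V = (V + V.T) / 2.0
        eig = np.linalg.eigvalsh(V)
        if eig.min() < -1e-8 * max(1.0, eig.max()):
            warnings.warn("covariance matrix is not positive semi-definite",
                          stacklevel=2)
            converged = False
    except linalg.LinAlgError:
        collinear = _collinear_terms(lik)
        raise linalg.LinAlgError(
            f"singular observed information; candidate collinear terms: {collinear}"
        )
    if not converged:
        warnings.warn(
            f"fit did not converge: max|score|={grad_norm:.3g} at loglik={ll:.6f}",
            stacklevel=2,
        )
    names = lik.names
    return FittedModel(
        spec=spec, knots=knots,
        params=pd.Series(theta, index=names),
        vcov=pd.DataFrame(V, index=names, columns=names),
        loglik=float(ll), converged=bool(converged), n_iter=n_iter,
        grad_norm=grad_norm, summary=lik.summary, reference=reference,
    )


def _collinear_terms(lik: _Likelihood) -> list[str]:
    q, r = np.linalg.qr(lik.X)
    diag = np.abs(np.diag(r))
    bad = diag < 1e-10 * diag.max()
    return [n for n, b in zip(lik.names, bad) if b]


# ---------------------------------------------------------------------------
# Post-estimation summaries


def emrr(
    model: FittedModel,
    profile: dict,
    profile_ref: dict,
    stratum_nonref: bool = False,
    t: float | None = None,
    level: float = 0.95,
) -> tuple[float, float, float]:
    """Excess mortality rate ratio between two covariate profiles.

    The EMRR is exp(η(x1) − η(x0)) evaluated on the given stratum; with
    time-dependent terms in the model it depends on ``t`` (required then).
    Returns (estimate, lower, upper) with a Wald interval on the log scale.
    """

    has_tvc = len(model.knots.tvc) > 0
    if t is None:
        if has_tvc:
            raise ValueError("model has time-dependent effects; supply t")
        t = 1.0
    X1, _ = model.design_row(profile, stratum_nonref, np.atleast_1d(float(t)))
    X0, _ = model.design_row(profile_ref, stratum_nonref, np.atleast_1d(float(t)))
    contrast = (X1 - X0)[0]
    log_ratio = float(contrast @ model.theta)
    se = float(np.sqrt(contrast @ model.vcov.to_numpy() @ contrast))
    z = stats.norm.ppf(0.5 + level / 2.0)
    return (np.exp(log_ratio), np.exp(log_ratio - z * se), np.exp(log_ratio + z * se))


def lr_test(nested: FittedModel, full: FittedModel) -> tuple[float, int, float]:
    """Likelihood-ratio test of a nested against a full model.

    Requires both fits to come from the identical data set (checked via
    the stored data summary) with the full model strictly larger.  Small
    negative statistics from numerical convergence noise are clipped to 0.
    """

    if nested.summary != full.summary:
        raise ValueError("models were fitted to different data sets")
    df = full.n_params - nested.n_params
    if df < 0:
        raise ValueError(
            f"full model has fewer parameters (nested={nested.n_params}, "
            f"full={full.n_params})"
        )
    statistic = 2.0 * (full.loglik - nested.loglik)
    if statistic < 0:
        if statistic < -1e-6 * (1 + abs(full.loglik)):
            raise ValueError(
                f"full model has lower likelihood ({full.loglik:.6f} < "
                f"{nested.loglik:.6f}); models are not nested or a fit failed"
            )
        warnings.warn(f"clipping small negative LR statistic {statistic:.3g} to 0",
                      stacklevel=2)
        statistic = 0.0
    p = 1.0 if (df == 0 or statistic == 0.0) else float(stats.chi2.sf(statistic, df))
    return float(statistic), int(df), p


def information_criteria(model: FittedModel) -> tuple[float, float]:
    """AIC = −2ℓ + 2p and BIC = −2ℓ + p·ln(n), n = number of subjects."""

    p = model.n_params
    ll = model.loglik
    n = model.summary.n_subjects
    aic = -2.0 * ll + 2.0 * p
    bic = -2.0 * ll + p * (np.log(n) if n > 0 else 0.0)
    return float(aic), float(bic)
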