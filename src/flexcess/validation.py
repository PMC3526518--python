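"""End-to-end validation experiments with known ground truth.

Each routine here exercises a whole analysis path against an independent
oracle — the published misclassification table, the closed-form
constant-hazard competing-risks solution, the algebraic equivalence of
joint and separate fits, and Monte-Carlo truth from the synthetic
generator — and returns plain dictionaries of summary numbers.  They are
used both by the test suite and by the reproducibility script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dataprep import expand_long
from .lifetables import LifeTable, SWEDISH_CVD_SCHEME
from .model import ModelSpec, emrr, fit, lr_test, model_from_theta, resolve_knots, ResolvedKnots
from .predict import crude_probabilities
from .sensitivity import load_reference_counts, sensitivity_table
from .splines import KnotVector
from .synthetic import (
    SimulationConfig,
    StratumTruth,
    simulate_cohort,
    true_crude_probabilities,
)

__all__ = [
    "misclassification_check",
    "joint_vs_separate",
    "constant_hazard_check",
    "parameter_recovery",
    "lr_calibration",
]


# ---------------------------------------------------------------------------
# Reference misclassification table


def misclassification_check() -> dict:
    """Recompute the published sensitivity table from its (O, E) counts.

    Returns the recomputed table plus the maximum absolute deviation from
    the published excess-death and percentage columns.
    """

    counts = load_reference_counts()
    out = sensitivity_table(counts, reductions=(0.10, 0.15, 0.20))
    dev_ed = np.abs(out["excess_deaths"] - counts["ed_printed"])
    devs = {
        k: np.abs(out[f"misclass_{k}"] - counts[f"p{k}_printed"])
        for k in (10, 15, 20)
    }
    return {
        "table": out,
        "max_dev_ed": float(dev_ed.max()),
        "max_dev_pct": float(np.max([d.max() for d in devs.values()])),
        "per_row_max_dev_pct": pd.concat(devs.values(), axis=1).max(axis=1),
    }


# ---------------------------------------------------------------------------
# Joint model with no shared parameters == separate per-stratum fits


def joint_vs_separate(seed: int = 11, n: int = 5000) -> dict:
    """The joint two-stratum model with fully cause-specific parameters is a
    linear reparameterization of two separate single-stratum fits, so the
    maximized total log likelihood and all per-stratum predictions must
    agree."""

    cfg = SimulationConfig(n=n, seed=seed)
    cohort, table = simulate_cohort(cfg)
    long = expand_long(cohort, SWEDISH_CVD_SCHEME, table, reference="other")

    # one knot vector shared by every baseline so the parameter spaces match
    knots = resolve_knots(ModelSpec(baseline_df=3), long)
    joint_spec = ModelSpec(
        baseline_df=3, baseline_knots=knots.baseline,
        cause_df=3, cause_knots=knots.baseline,
        shared=("x", "period"), cause_specific=("x", "period"),
    )
    joint = fit(joint_spec, long, reference="other")

    sep_spec = ModelSpec(baseline_df=3, baseline_knots=knots.baseline,
                         shared=("x", "period"), cause_shift=False)
    sep = {s: fit(sep_spec, long[long["stratum"] == s].reset_index(drop=True))
           for s in ("other", "cvd")}
    ll_sep = sum(m.loglik for m in sep.values())

    grid = np.linspace(0.25, 15.0, 60)
    profiles = [{"x": 0.0, "period": 0.0}, {"x": 1.0, "period": 1.0}]
    max_rel = 0.0
    for prof in profiles:
        for s, nonref in (("other", False), ("cvd", True)):
            lam_j = joint.excess_hazard(prof, nonref, grid)
            lam_s = sep[s].excess_hazard(prof, False, grid)
            max_rel = max(max_rel, float(np.max(np.abs(lam_j - lam_s)
                                                / np.maximum(np.abs(lam_s), 1e-12))))
    return {
        "loglik_joint": joint.loglik,
        "loglik_separate": ll_sep,
        "loglik_absdiff": abs(joint.loglik - ll_sep),
        "rate_max_reldiff": max_rel,
        "converged": joint.converged and all(m.converged for m in sep.values()),
    }


# ---------------------------------------------------------------------------
# Constant-hazard closed form


def _flat_lifetable(rates: dict, sex="female", years=(1960, 2010)) -> LifeTable:
    ages = np.arange(0, 100)
    rows = []
    for cause, r in rates.items():
        for y in range(years[0], years[1] + 1):
            rows.append(pd.DataFrame({"age": ages, "sex": sex, "year": y,
                                      "cause": cause, "rate": r}))
    return LifeTable(pd.concat(rows, ignore_index=True))


def constant_hazard_check(n: int = 1000) -> dict:
    """Crude probabilities under flat hazards against the closed form
    λ_j/Λ · (1 − e^{−Λt}), plus the accounting identity and the
    order-of-convergence of the trapezoidal rule."""

    lam = {"other": 0.10, "cvd": 0.02}
    hstar = {"other": 0.03, "cvd": 0.01}
    table = _flat_lifetable(hstar)
    knots = ResolvedKnots(baseline=KnotVector((np.log(0.01), np.log(20.0))),
                          cause=None, tvc=())
    spec = ModelSpec(baseline_df=1, baseline_knots=knots.baseline,
                     cause_shift=True)
    theta = [np.log(lam["other"]), 1.0, np.log(lam["cvd"] / lam["other"])]
    model = model_from_theta(spec, knots, theta, names=["cons", "rcs1", "c"],
                             reference="other")

    times = np.linspace(1.0, 15.0, 15)
    total = sum(lam.values()) + sum(hstar.values())
    closed = {s: lam[s] / total * (-np.expm1(-total * times)) for s in lam}
    closed_other = sum(hstar.values()) / total * (-np.expm1(-total * times))

    def run(n_sub):
        curve = crude_probabilities(
            model, table, {}, age_dx=60.0, sex="female", year_dx=1980,
            strata=["cvd", "other"], times=times, n=n_sub, reference="other",
            ci=False)
        err = max(float(np.max(np.abs(curve.crude[s] - closed[s]))) for s in lam)
        err = max(err, float(np.max(np.abs(curve.crude_other - closed_other))))
        identity = float(np.max(np.abs(
            curve.surv + curve.crude["cvd"] + curve.crude["other"]
            + curve.crude_other - 1.0)))
        return err, identity

    err_n, identity_n = run(n)
    err_2n, _ = run(2 * n)
    return {
        "max_abs_err": err_n,
        "identity_max_dev": identity_n,
        "err_double_n": err_2n,
        "error_ratio": err_n / err_2n if err_2n > 0 else np.inf,
    }


# ---------------------------------------------------------------------------
# Parameter recovery and CI coverage


def _recovery_config(n: int, seed: int) -> SimulationConfig:
    return SimulationConfig(n=n, seed=seed)  # defaults ARE the truth


def parameter_recovery(seed: int = 2012, n_rep: int = 200, n: int = 20_000,
                       crude_t: float = 10.0) -> dict:
    """Simulate-fit replicates: CI coverage of the true log-EMRRs, relative
    error of the EMRR point estimates, and coverage of the delta-method
    interval for the crude probability of the rarer component."""

    rng = np.random.default_rng(seed)
    true_emrr = {"other": 0.5, "cvd": 2.0}
    spec = ModelSpec(baseline_df=2, cause_df=2, shared=("x", "period"),
                     cause_specific=("x",))
    cover = {"other": 0, "cvd": 0}
    rel_err = []
    crude_cover = 0
    crude_abs_err = []
    n_fit = 0
    profile_truth = {"x": 1.0, "period": 0.0}
    for _ in range(n_rep):
        rep_seed = int(rng.integers(2**31))
        cfg = _recovery_config(n, rep_seed)
        cohort, table = simulate_cohort(cfg)
        long = expand_long(cohort, SWEDISH_CVD_SCHEME, table, reference="other")
        model = fit(spec, long, reference="other")
        if not model.converged:
            continue
        n_fit += 1
        for s, nonref in (("other", False), ("cvd", True)):
            est, lo, hi = emrr(model, {"x": 1, "period": 0}, {"x": 0, "period": 0},
                               stratum_nonref=nonref)
            if lo <= true_emrr[s] <= hi:
                cover[s] += 1
            rel_err.append(abs(est - true_emrr[s]) / true_emrr[s])
        truth = true_crude_probabilities(cfg, profile_truth, age_dx=60.0,
                                         t=[crude_t], n=100_000)
        curve = crude_probabilities(
            model, table, profile_truth, age_dx=60.0, sex=cfg.sex, year_dx=1980,
            strata=["cvd", "other"], times=[crude_t], n=500, reference="other")
        lo, hi = (curve.ci["cvd"][0][0], curve.ci["cvd"][1][0])
        if lo <= truth["cvd"][0] <= hi:
            crude_cover += 1
        crude_abs_err.append(abs(float(curve.crude["cvd"][0]) - truth["cvd"][0]))
    return {
        "n_converged": n_fit,
        "coverage_other": cover["other"] / n_fit,
        "coverage_cvd": cover["cvd"] / n_fit,
        "coverage_pooled": (cover["other"] + cover["cvd"]) / (2 * n_fit),
        "median_rel_err": float(np.median(rel_err)),
        "crude_ci_coverage": crude_cover / n_fit,
        "crude_median_abs_err": float(np.median(crude_abs_err)),
    }


# ---------------------------------------------------------------------------
# Likelihood-ratio test calibration under the null


def _single_stratum_config(n: int, seed: int) -> SimulationConfig:
    return SimulationConfig(
        n=n, seed=seed,
        strata=(StratumTruth(name="other", bg_a=2e-5, bg_b=0.095,
                             rho=0.08, kappa=0.8, betas={}),),
        shared_betas={},
        covariates={"z": ("bernoulli", 0.5)},
    )


def _single_stratum_long(cohort: pd.DataFrame, table: LifeTable,
                         stratum: str = "other") -> pd.DataFrame:
    long = cohort.copy()
    long["stratum"] = stratum
    long["c"] = 0
    long["d"] = long["event"].astype(int)
    long["entry"] = 0.0
    time = long["time"].to_numpy(float)
    age = long["age_dx"].to_numpy(float) + time
    year = (long["year_dx"].to_numpy(int) + np.floor(time)).astype(int)
    long["expected_rate"] = table.lookup_many(
        age, long["sex"].to_numpy(), year,
        np.full(len(long), stratum, dtype=object))
    return long


def lr_calibration(seed: int = 500, n_rep: int = 500, n: int = 1500,
                   alpha: float = 0.05) -> dict:
    """Null rejection rate of the LR test for a covariate with no effect."""

    rng = np.random.default_rng(seed)
    nested_spec = ModelSpec(baseline_df=2, cause_shift=False)
    full_spec = ModelSpec(baseline_df=2, shared=("z",), cause_shift=False)
    reject = 0
    n_done = 0
    for _ in range(n_rep):
        cfg = _single_stratum_config(n, int(rng.integers(2**31)))
        cohort, table = simulate_cohort(cfg)
        long = _single_stratum_long(cohort, table)
        nested = fit(nested_spec, long)
        full = fit(full_spec, long)
        if not (nested.converged and full.converged):
            continue
        _, _, p = lr_test(nested, full)
        n_done += 1
        if p < alpha:
            reject += 1
    return {"n_replicates": n_done, "rejection_rate": reject / n_done,
            "alpha": alpha}
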