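"""Model specification, likelihood, fitting, and post-fit summaries."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from flexcess.dataprep import expand_long
from flexcess.lifetables import SWEDISH_CVD_SCHEME
from flexcess.model import (
    DataSummary,
    ModelSpec,
    ResolvedKnots,
    _Likelihood,
    emrr,
    fit,
    information_criteria,
    log_likelihood,
    lr_test,
    model_from_theta,
    resolve_knots,
)
from flexcess.splines import KnotVector

UNIT_KNOTS = ResolvedKnots(baseline=KnotVector((np.log(0.01), np.log(20.0))),
                           cause=None, tvc=())


def _unit_exponential_model(rate=1.0, shift=None):
    """A model with Θ = rate·t (and optional non-reference shift)."""

    spec = ModelSpec(baseline_df=1, baseline_knots=UNIT_KNOTS.baseline,
                     cause_shift=shift is not None)
    if shift is None:
        return model_from_theta(spec, UNIT_KNOTS, [np.log(rate), 1.0],
                                names=["cons", "rcs1"])
    return model_from_theta(spec, UNIT_KNOTS, [np.log(rate), 1.0, shift],
                            names=["cons", "rcs1", "c"])


class TestLinearPredictorAndHazard:
    def test_reference_stratum_baseline_only(self):
        m = _unit_exponential_model(rate=0.5, shift=1.3)
        t = np.array([0.5, 1.0, 4.0])
        eta_ref = m.linear_predictor({}, False, t)
        np.testing.assert_allclose(eta_ref, np.log(0.5) + np.log(t))

    def test_zero_theta_gives_unit_cumulative_hazard(self):
        spec = ModelSpec(baseline_df=1, baseline_knots=UNIT_KNOTS.baseline,
                         cause_shift=False)
        m = model_from_theta(spec, UNIT_KNOTS, [0.0, 0.0], names=["cons", "rcs1"])
        np.testing.assert_allclose(m.cumulative_excess({}, False, [0.3, 2.0]), 1.0)
        # flat cumulative hazard implies zero excess hazard
        np.testing.assert_allclose(m.excess_hazard({}, False, [0.3, 2.0]), 0.0)

    def test_proportional_cause_shift_is_constant_over_time(self):
        m = _unit_exponential_model(rate=0.5, shift=1.3)
        t = np.array([0.2, 1.0, 7.0])
        diff = (m.linear_predictor({}, True, t) - m.linear_predictor({}, False, t))
        np.testing.assert_allclose(diff, 1.3)

    def test_unit_exponential_excess_hazard_is_one(self):
        m = _unit_exponential_model(rate=1.0)
        np.testing.assert_allclose(m.excess_hazard({}, False, [0.1, 1.0, 9.0]), 1.0)

    def test_hazard_matches_numeric_derivative_of_cumulative(self):
        # oracle: central finite difference of Θ for an arbitrary model
        knots = ResolvedKnots(
            baseline=KnotVector((np.log(0.05), np.log(1.0), np.log(12.0))),
            cause=None, tvc=())
        spec = ModelSpec(baseline_df=2, baseline_knots=knots.baseline,
                         cause_shift=False)
        m = model_from_theta(spec, knots, [-1.2, 0.9, 0.15],
                             names=["cons", "rcs1", "rcs2"])
        t = np.linspace(0.3, 10, 25)
        h = 1e-6
        fd = (m.cumulative_excess({}, False, t + h)
              - m.cumulative_excess({}, False, t - h)) / (2 * h)
        np.testing.assert_allclose(m.excess_hazard({}, False, t), fd,
                                   rtol=1e-6)


class TestLogLikelihood:
    def _long(self, time, d, hstar, c=None, **covs):
        n = len(time)
        df = pd.DataFrame({"id": np.arange(n), "stratum": "all",
                           "c": c if c is not None else np.zeros(n, int),
                           "d": d, "time": time, "entry": 0.0,
                           "expected_rate": hstar})
        for k, v in covs.items():
            df[k] = v
        return df

    def test_all_censored_is_pure_survival_contribution(self):
        time = np.array([1.0, 2.0, 3.0])
        long = self._long(time, [0, 0, 0], 0.02)
        spec = ModelSpec(baseline_df=1, baseline_knots=UNIT_KNOTS.baseline,
                         cause_shift=False)
        theta = [np.log(0.3), 1.0]  # Θ = 0.3 t
        ll = log_likelihood(spec, theta, long, knots=UNIT_KNOTS)
        assert ll == pytest.approx(-0.3 * time.sum())

    def test_zero_expected_rate_equals_all_cause_likelihood(self):
        # oracle: d·ln λ − Θ computed directly for the exponential model
        time = np.array([0.5, 1.5, 2.0, 4.0])
        d = np.array([1, 0, 1, 0])
        long = self._long(time, d, 0.0)
        spec = ModelSpec(baseline_df=1, baseline_knots=UNIT_KNOTS.baseline,
                         cause_shift=False)
        rate = 0.7
        ll = log_likelihood(spec, [np.log(rate), 1.0], long, knots=UNIT_KNOTS)
        direct = (d * np.log(rate) - rate * time).sum()
        assert ll == pytest.approx(direct, abs=1e-10)

    def test_doubling_records_doubles_loglik(self):
        time = np.array([0.5, 1.5, 2.0])
        d = np.array([1, 0, 1])
        long = self._long(time, d, 0.05)
        spec = ModelSpec(baseline_df=1, baseline_knots=UNIT_KNOTS.baseline,
                         cause_shift=False)
        theta = [np.log(0.4), 1.0]
        ll1 = log_likelihood(spec, theta, long, knots=UNIT_KNOTS)
        ll2 = log_likelihood(spec, theta,
                             pd.concat([long, long.assign(id=long["id"] + 10)],
                                       ignore_index=True), knots=UNIT_KNOTS)
        assert ll2 == pytest.approx(2 * ll1)

    def test_score_matches_numeric_gradient(self):
        rng = np.random.default_rng(5)
        n = 200
        time = rng.uniform(0.2, 10, n)
        d = rng.binomial(1, 0.5, n)
        long = self._long(time, d, 0.03, x=rng.binomial(1, 0.4, n).astype(float))
        spec = ModelSpec(baseline_df=2, shared=("x",), cause_shift=False)
        knots = resolve_knots(spec, long)
        lik = _Likelihood(spec, knots, long)
        theta = np.array([-0.8, 0.9, 0.1, 0.3])
        g = lik.score(theta)
        fd = np.empty_like(g)
        for k in range(theta.size):
            h = 1e-6
            tp, tm = theta.copy(), theta.copy()
            tp[k] += h
            tm[k] -= h
            fd[k] = (lik.loglik(tp) - lik.loglik(tm)) / (2 * h)
        np.testing.assert_allclose(g, fd, rtol=1e-5, atol=1e-7)


class TestFit:
    def test_refit_from_optimum_is_a_fixed_point(self, single_stratum_long):
        spec = ModelSpec(baseline_df=2, shared=("z",), cause_shift=False)
        m1 = fit(spec, single_stratum_long)
        m2 = fit(spec, single_stratum_long, init=m1.theta)
        assert m2.n_iter <= 2
        assert m2.loglik == pytest.approx(m1.loglik, abs=1e-6)

    def test_vcov_is_symmetric_psd_and_sized(self, single_stratum_long):
        spec = ModelSpec(baseline_df=2, shared=("z",), cause_shift=False)
        m = fit(spec, single_stratum_long)
        V = m.vcov.to_numpy()
        assert V.shape == (m.n_params, m.n_params)
        np.testing.assert_allclose(V, V.T, atol=1e-12)
        assert np.linalg.eigvalsh(V).min() > 0
        assert m.converged

    def test_matches_royston_parmar_reference_implementation(
            self, single_stratum_long, tmp_path):
        """With h*=0 the model is the standard flexible parametric survival
        model; an independent reference implementation (R flexsurv) fitted
        with identical knots must reach the same maximum."""

        spec = ModelSpec(baseline_df=2, cause_shift=False)
        m = fit(spec, single_stratum_long)
        csv = tmp_path / "surv.csv"
        single_stratum_long[["time", "d"]].rename(columns={"d": "event"}).to_csv(
            csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(flexsurv))
            d <- read.csv("{csv}")
            f <- flexsurvspline(Surv(time, event) ~ 1, data = d, k = 1,
                                scale = "hazard")
            cat(sprintf("%.10f\\n", logLik(f)))
            cat(sprintf("%.10f\\n", coef(f)))
        """))
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, check=True)
        vals = [float(v) for v in out.stdout.split()]
        r_loglik, r_coef = vals[0], np.array(vals[1:])
        assert m.loglik == pytest.approx(r_loglik, abs=1e-3)
        np.testing.assert_allclose(m.theta, r_coef, atol=5e-3)

    def test_bad_init_length_rejected(self, single_stratum_long):
        spec = ModelSpec(baseline_df=2, cause_shift=False)
        with pytest.raises(ValueError, match="init"):
            fit(spec, single_stratum_long, init=[0.0])

    def test_no_events_errors(self, single_stratum_long):
        none = single_stratum_long.assign(d=0)
        with pytest.raises(ValueError, match="no events"):
            fit(ModelSpec(baseline_df=2, cause_shift=False), none)


class TestEmrr:
    def test_zero_contrast_is_unity_with_degenerate_interval(self):
        m = _unit_exponential_model(rate=0.5, shift=0.3)
        est, lo, hi = emrr(m, {}, {}, stratum_nonref=False)
        assert (est, lo, hi) == (1.0, 1.0, 1.0)

    def test_published_interval_back_computation(self):
        """A reported EMRR of 5.32 (3.51-8.06) implies se = (ln 8.06 − ln
        3.51)/(2·1.96); rebuilding the interval from that se must return the
        printed bounds."""

        log_est = np.log(5.32)
        se = (np.log(8.06) - np.log(3.51)) / (2 * 1.9599639845400545)
        spec = ModelSpec(baseline_df=1, baseline_knots=UNIT_KNOTS.baseline,
                         shared=("g",), cause_shift=False)
        V = np.zeros((3, 3))
        V[2, 2] = se**2
        m = model_from_theta(spec, UNIT_KNOTS, [0.0, 1.0, log_est],
                             names=["cons", "rcs1", "g"], vcov=V)
        est, lo, hi = emrr(m, {"g": 1.0}, {"g": 0.0})
        assert est == pytest.approx(5.32)
        assert lo == pytest.approx(3.51, abs=5e-3)
        assert hi == pytest.approx(8.06, abs=5e-3)

    def test_proportional_model_emrr_constant_in_time(self, small_cohort):
        cohort, table = small_cohort
        long = expand_long(cohort, SWEDISH_CVD_SCHEME, table, reference="other")
        m = fit(ModelSpec(baseline_df=2, cause_df=2, shared=("x",),
                          cause_specific=("x",)), long, reference="other")
        at1 = emrr(m, {"x": 1}, {"x": 0}, stratum_nonref=True, t=1.0)
        at9 = emrr(m, {"x": 1}, {"x": 0}, stratum_nonref=True, t=9.0)
        assert at1[0] == pytest.approx(at9[0], rel=1e-12)

    def test_time_dependent_model_requires_t(self, single_stratum_long):
        m = fit(ModelSpec(baseline_df=2, shared=("z",), tvc=(("z", 1),),
                          cause_shift=False), single_stratum_long)
        with pytest.raises(ValueError, match="time-dependent"):
            emrr(m, {"z": 1}, {"z": 0})
        e1 = emrr(m, {"z": 1}, {"z": 0}, t=1.0)[0]
        e5 = emrr(m, {"z": 1}, {"z": 0}, t=5.0)[0]
        assert e1 != e5  # effect varies over follow-up


class TestLrTestAndIc:
    def test_identical_models_give_zero_statistic_p_one(self, single_stratum_long):
        m = fit(ModelSpec(baseline_df=2, cause_shift=False), single_stratum_long)
        stat, df, p = lr_test(m, m)
        assert stat == 0.0 and df == 0 and p == 1.0

    def test_df_is_parameter_count_difference(self, single_stratum_long):
        nested = fit(ModelSpec(baseline_df=2, cause_shift=False),
                     single_stratum_long)
        full = fit(ModelSpec(baseline_df=2, shared=("z",), tvc=(("z", 1),),
                             cause_shift=False), single_stratum_long)
        stat, df, p = lr_test(nested, full)
        assert df == full.n_params - nested.n_params == 2
        assert stat >= 0 and 0 <= p <= 1

    def test_different_data_rejected(self, single_stratum_long):
        m1 = fit(ModelSpec(baseline_df=2, cause_shift=False),
                 single_stratum_long)
        m2 = fit(ModelSpec(baseline_df=2, cause_shift=False),
                 single_stratum_long.iloc[:-2].reset_index(drop=True))
        with pytest.raises(ValueError, match="different data"):
            lr_test(m1, m2)

    def test_information_criteria_formulas(self, single_stratum_long):
        m = fit(ModelSpec(baseline_df=2, shared=("z",), cause_shift=False),
                single_stratum_long)
        aic, bic = information_criteria(m)
        n = m.summary.n_subjects
        assert aic == pytest.approx(-2 * m.loglik + 2 * m.n_params)
        assert bic == pytest.approx(-2 * m.loglik + m.n_params * np.log(n))
        # AIC difference identity against a smaller model
        m0 = fit(ModelSpec(baseline_df=2, cause_shift=False),
                 single_stratum_long)
        aic0, _ = information_criteria(m0)
        dll = m.loglik - m0.loglik
        assert aic - aic0 == pytest.approx(-2 * dll + 2 * (m.n_params - m0.n_params))


class TestJointModelStructure:
    def test_time_rescaling_equivariance(self, single_stratum_long):
        """Measuring time in different units must not change the model:
        multiplying every survival time by c translates all log-time knots
        by ln c, scales the fitted hazard by 1/c, and shifts the maximized
        log likelihood by exactly −D·ln c (events D) when h* = 0."""

        long = single_stratum_long
        m1 = fit(ModelSpec(baseline_df=2, cause_shift=False), long)
        c = 2.0
        scaled = long.assign(time=long["time"] * c)
        m2 = fit(ModelSpec(baseline_df=2, cause_shift=False), scaled)
        np.testing.assert_allclose(
            np.asarray(m2.knots.baseline.values),
            np.asarray(m1.knots.baseline.values) + np.log(c), atol=1e-12)
        D = long["d"].sum()
        assert m2.loglik == pytest.approx(m1.loglik - D * np.log(c), abs=1e-4)
        t = np.linspace(0.5, 10, 20)
        np.testing.assert_allclose(m2.excess_hazard({}, False, c * t),
                                   m1.excess_hazard({}, False, t) / c,
                                   rtol=1e-4)

    def test_total_model_emrr_approaches_majority_stratum_emrr(self):
        """When one stratum carries a small share of the events, EMRRs from
        an unpartitioned total-excess model approach the majority stratum's
        EMRRs; the log-EMRR gap shrinks as that share goes to zero."""

        from flexcess.synthetic import SimulationConfig, StratumTruth, simulate_cohort

        def gap(rho_cvd, seed):
            cfg = SimulationConfig(
                n=20_000, seed=seed,
                strata=(StratumTruth(name="cvd", bg_a=5e-6, bg_b=0.105,
                                     rho=rho_cvd, kappa=1.2,
                                     betas={"x": np.log(2.0)}),
                        StratumTruth(name="other", bg_a=2e-5, bg_b=0.095,
                                     rho=0.08, kappa=0.8,
                                     betas={"x": np.log(0.5)})),
                shared_betas={}, covariates={"x": ("bernoulli", 0.5)})
            cohort, table = simulate_cohort(cfg)
            long = expand_long(cohort, SWEDISH_CVD_SCHEME, table,
                               reference="other")
            joint = fit(ModelSpec(baseline_df=2, cause_df=2, shared=("x",),
                                  cause_specific=("x",)), long,
                        reference="other")
            # total-excess model: all-cause events against summed rates
            other = long[long["stratum"] == "other"].reset_index(drop=True)
            cvd = long[long["stratum"] == "cvd"].reset_index(drop=True)
            total = other.assign(
                d=(other["d"].to_numpy() + cvd["d"].to_numpy()),
                expected_rate=(other["expected_rate"].to_numpy()
                               + cvd["expected_rate"].to_numpy()))
            tot = fit(ModelSpec(baseline_df=2, shared=("x",),
                                cause_shift=False), total)
            e_other = emrr(joint, {"x": 1}, {"x": 0}, stratum_nonref=False)[0]
            e_total = emrr(tot, {"x": 1}, {"x": 0})[0]
            return abs(np.log(e_total) - np.log(e_other))

        assert gap(rho_cvd=0.0004, seed=21) < gap(rho_cvd=0.02, seed=21)

    def test_product_covariate_columns(self, small_cohort):
        # restricted higher-order interactions via linear product columns
        cohort, table = small_cohort
        long = expand_long(cohort, SWEDISH_CVD_SCHEME, table, reference="other")
        m = fit(ModelSpec(baseline_df=2, shared=("x", "period", "x*period")),
                long, reference="other")
        assert "x*period" in m.params.index
        assert m.converged

    def test_data_summary_equality_semantics(self):
        a = DataSummary(5, 10, ("cvd", "other"), (("cvd", 2), ("other", 3)), 50.0)
        b = DataSummary(5, 10, ("cvd", "other"), (("cvd", 2), ("other", 3)), 50.0)
        c = DataSummary(5, 10, ("cvd", "other"), (("cvd", 1), ("other", 4)), 50.0)
        assert a == b and a != c
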