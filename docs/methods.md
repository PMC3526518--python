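# Methods

## Model

The package works on the relative-survival scale.  The all-cause hazard
of a patient is `h(t) = h*(t) + λ(t)`: a known background (expected) rate
`h*` from population life tables plus an excess rate `λ` attributable —
directly or indirectly — to the diagnosis.  To study one component of
the excess (say cardiovascular deaths occurring in excess of the
population rate), both sides are stratified by mutually exclusive
recorded-cause groups `j`:

    H(t) = Σ_j H*_j(t) + Σ_j Θ_j(t),

with `Θ_j` the cumulative excess hazard of component `j`.  Each `ln Θ_j`
is modelled linearly in restricted cubic splines of `ln t` and
covariates:

    ln Θ_j(t; x) = s(ln t; γ0, k0) + xᵀβ
                   + c_j [ β_c + s(ln t; γ_c, k_c) + xᵀβ_c ]
                   + Σ_i s(ln t; γ_i, k_i) x_i

`c_j` is 1 on non-reference stratum rows.  The deviation spline
`s(ln t; γ_c, k_c)` lets the non-reference baseline vary freely; omitting
it (and `xᵀβ_c`) forces proportionality between components.  The final
sum holds ordinary time-dependent covariate effects.  Dropping all
stratum terms recovers the single-outcome flexible parametric
relative-survival model.

### Likelihood

Each subject appears once per stratum (long format).  Row `(i, j)`
contributes

    ℓ_ij = d_ij · ln( h*_ij + λ_j(t_i) ) − Θ_j(t_i),

where `d_ij` flags death with recorded cause in stratum `j`,
`λ_j = Θ_j · (∂η_j/∂ ln t) / t`, and `h*_ij` is the life-table rate at
the subject's exit cell (attained age and calendar year advanced with
follow-up, floored to 1-year cells).  Expected cumulative hazards are
parameter-free and dropped.  Delayed entry is supported by adding
`Θ_j(t_entry)` back (unused by the default cohort design, which follows
subjects from diagnosis).

A fitted excess hazard may legitimately be negative (patients can have
*lower* mortality than the comparison population), but the total hazard
`h* + λ` must be positive wherever a death occurred.  Below a floor of
1e-12 the log is continued linearly, which keeps the surface smooth,
heavily penalizes invalid regions, and leaves the score informative so
the optimizer retreats on its own; no hard constraints are imposed.

### Splines

Restricted (natural) cubic splines in the raw truncated-power
parameterization: `df` basis columns from `df + 1` knots, the first
column the identity, each interior knot contributing
`(x−k_j)₊³ − a_j(x−k_min)₊³ − (1−a_j)(x−k_max)₊³` with
`a_j = (k_max−k_j)/(k_max−k_min)`.  The basis is C2 everywhere and
exactly linear beyond the boundary knots, so extrapolation on the log
cumulative hazard scale is log-linear.  Columns are **not**
orthogonalized: some reference implementations orthogonalize by default,
which changes printed coefficients but not the spanned space.  Fitted γ
are therefore basis-dependent while every prediction is invariant; users
comparing coefficients across software should compare predictions
instead.

Knots are placed at centiles of the *uncensored* log event times:
equally spaced from the 0th to the 100th centile by default (5 df →
0/20/40/60/80/100; 3 df → 0/33/67/100), with explicit schemes (e.g.
5/25/50/75/95) available for continuous covariates.  Two centiles
landing on the same value raise an error rather than silently merging —
reproducibility over convenience.

### Fitting

Newton iterations with backtracking line search; the observed
information is obtained by central finite differences of the analytic
score (step `1e-6·(1+|θ_k|)`).  Non-positive-definite information
triggers a ridged solve and ultimately an L-BFGS restart with Newton
polishing.  Starting values are zeros except the baseline: intercept
`ln((D − E)/PT)` (events minus expected events over person-time — a
crude exponential excess rate) and slope 1 on the linear log-time
column, i.e. `Θ ≈ rate · t`.  Convergence requires
`max|score| / (1 + |ℓ|) < 1e-9`; the convergence flag is honest and a
failed fit warns with the final score norm.  The covariance matrix is
the inverse observed information.  Everything is deterministic; no
seeds are involved in fitting.

AIC and BIC use `−2ℓ + 2p` and `−2ℓ + p ln n` with `n` the number of
**subjects** (not long rows, not events): the long format duplicates
subjects purely as a computational device, so subjects are the natural
unit of information.  This choice matters only for BIC comparisons
across software.

## Post-estimation

Component crude probabilities

    Cr_j(t) = ∫₀ᵗ S*(u) R(u) λ_j(u) du,
    Cr_bg(t) = ∫₀ᵗ S*(u) R(u) h*(u) du,

with `R = exp(−Σ_j Θ_j)` and `S*` from the cause-summed expected rates,
are evaluated by the trapezoidal rule on a uniform grid of `n`
sub-intervals (default 1000; the rule is O(1/n²) for smooth integrands).
Because the integrands involve splines of `ln u`, the grid starts at
`t_min` = 1 day rather than 0.  The `[0, t_min]` sliver is added in
closed form: `∫₀^{t_min} λ_j = Θ_j(t_min)` exactly (robust even when
`λ_j` diverges like `t^{γ−1}` at the origin), damped by `S*R(t_min)`;
the background sliver is the rectangle `t_min·h*(t_min)`.  The summed
components then satisfy the accounting identity
`S*(t)R(t) + Σ_j Cr_j(t) + Cr_bg(t) = 1` to quadrature accuracy (~1e-7
at n = 1000 for smooth profiles; the identity degrades gracefully, to
~1e-3, for fitted hazards that are weakly singular at t = 0).
Marginality — components summing to the all-excess crude probability —
holds exactly by linearity of the quadrature.

Expected-rate trajectories `h*_j(u)` advance attained age and calendar
year stepwise in 1-year cells, the same convention used when attaching
rates to the likelihood, so estimation and prediction share no hidden
discrepancy.  Ages above the table maximum are capped there; missing
cells raise rather than impute.

Confidence intervals use the delta method: gradients of the log
functional with respect to θ̂ by central finite differences (step
`1e-5·(1+|θ_k|)`), variance `gᵀVg`, interval formed on the log scale
and back-transformed.  The log scale keeps rates and probabilities
positive; values are floored at machine epsilon before taking logs.  The
exact transformation used by earlier reference software for crude
probabilities is not publicly specified; the log scale here is this
package's own documented choice.  For functionals linear in θ the
identity-scale option reproduces the exact normal interval.

EMRRs are computed as `exp(η(x₁) − η(x₀))` from the difference of two
design rows, which automatically cancels baseline terms and picks up
time-dependent terms when `t` is supplied (required if the model has
any).

## Synthetic cohorts

The generator emulates the structure of a registry breast-cancer cohort:
women diagnosed 1973–1992 at ages 40–79 (uniform), administratively
censored at 15 years, two cause strata.  Background rates are Gompertz
in attained age — cvd `5e-6·exp(0.105·age)`, other
`2e-5·exp(0.095·age)`, giving ~2.7/1000 py cvd mortality at 60 —
emitted to the estimator as a matching life table.  Excess hazards are
Weibull: cvd `Θ = 0.004·t^1.2` (rising, the late treatment-effect
shape), other `Θ = 0.08·t^0.8` (high early, declining — the typical
cancer shape), with log-linear true EMRRs (defaults: 0.5/2.0 for a
binary covariate, 0.8 shared calendar effect).  Event times are drawn by
inversion of each cause-specific cumulative hazard (latent failure
times; recorded cause = argmin) with the same stepwise attained-age
convention as the life-table lookups; the closed-form cumulative hazards
also yield exact crude probabilities under the truth, used as oracles.

What the generator does **not** emulate: informative censoring,
covariate-dependent diagnosis age, life tables varying by calendar year,
coding error in causes of death, or the marginals of any real registry.
Passing tests therefore demonstrate correctness of the estimator under a
correctly specified model of realistic magnitude — not robustness to the
misspecifications real data carry.

## Validation experiments and problem sizes

- Joint-vs-separate equivalence on one 5,000-subject cohort: the joint
  model with fully cause-specific parameters is a linear
  reparameterization of two separate fits, so maximized likelihoods
  agree to ~1e-12 and per-stratum predicted rates to ~1e-10.
- Constant-hazard oracle at n = 1000 sub-intervals against
  `λ_j/Λ·(1−e^{−Λt})`; the quadrature error falls ~4× when n doubles.
- Parameter recovery: 200 replicates of n = 20,000 (the scale at which
  a registry analysis of this design is comfortably powered); 95% CI
  coverage of both true log-EMRRs and of the 10-year crude probability
  lands near nominal, median relative EMRR error ~3%.
- LR-test calibration: 500 null replicates of n = 1,500 single-stratum
  cohorts; rejection at α = 0.05 runs ~0.04 (slightly conservative in
  this finite-sample design, inside the expected binomial band).
- A single-stratum fit with `h* ≡ 0` is cross-checked against an
  independent reference implementation of the flexible parametric
  survival model (R `flexsurv::flexsurvspline`) on identical knots:
  maximized likelihoods agree to <1e-3.

## Known limitations

- No penalized or monotonicity-constrained splines; no cure-fraction
  extension; no Fine–Gray subdistribution modelling (crude probabilities
  are obtained from cause-partitioned excess hazards instead).
- Expected rates are taken at the exit cell in the likelihood (standard
  practice); rates varying *within* a subject's follow-up enter only
  through the prediction trajectories.
- Life-table cells are single-year and unsmoothed; rare-cause strata may
  need smoothed expected rates before this machinery is reliable.
- The misclassification sensitivity analysis is a deterministic
  what-if computation, not a probabilistic bias analysis.
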