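# flexcess

Flexible parametric survival models that **partition the excess mortality**
of a patient cohort into mutually exclusive cause-specific components —
for example, excess cardiovascular mortality versus the remaining excess
mortality after a cancer diagnosis — with post-estimation excess rates,
excess mortality rate ratios (EMRRs), and crude probabilities of death in
the presence of competing causes.

## Who this is for

Registry-based cancer survival studies usually work on the relative
survival scale: the patients' all-cause survival `S(t)` is compared with
the expected survival `S*(t)` of a matched disease-free population, so
that the *excess* hazard `λ(t) = h(t) − h*(t)` captures everything
attributable to the diagnosis without relying on cause-of-death coding.
But some questions — most prominently late treatment-related
cardiovascular mortality — concern one *component* of that excess.  Such
deaths cannot be identified from death certificates alone (nobody can say
which cardiovascular deaths would not have happened absent the diagnosis),
yet they can be estimated **in aggregate** by stratifying both the
expected rates and the excess hazard by recorded cause group.

## The model

With cause strata `j` (e.g. cvd / other), cause-stratified life tables
supply known expected rates `h*_j`, and the log cumulative excess hazard
of each stratum is modelled with restricted cubic splines `s(·)` of log
time:

```
ln Θ_j(t; x) = s(ln t; γ0, k0) + xᵀβ
               + c_j [ β_c + s(ln t; γ_c, k_c) + xᵀβ_c ]
               + Σ_i s(ln t; γ_i, k_i) x_i
```

where `c_j` indicates the non-reference stratum.  Fitting is by maximum
likelihood on a *long-format* data set (one row per subject per stratum;
each row contributes `d ln(h* + λ(t)) − Θ(t)`), so covariate effects can
be **shared** across strata (`β`) or **cause-specific** (`β_c`), and the
final sum holds time-dependent (non-proportional) effects.  Post
estimation, the crude probability of dying from component `j` by time `t`,

```
Cr_j(t) = ∫₀ᵗ S*(u) R(u) λ_j(u) du,      R(u) = exp(−Σ_j Θ_j(u)),
```

is computed by numerical integration, with delta-method 95% confidence
intervals.

## Worked example

`examples/02_simulate_and_fit.py` simulates a 20,000-subject cohort in
which the true EMRRs of a binary covariate `x` are 0.5 on the "other"
excess component and 2.0 on the cvd component, with a calendar-period
effect of 0.8 shared by both, then fits the joint model:

```
simulated 20000 women, 12551 deaths
long format: 40000 rows (2 per subject), 3384 cvd deaths
loglik -48103.95, 9 parameters, AIC 96225.9, BIC 96297.0, converged=True
EMRR of x on excess other mortality: 0.52 (95% CI 0.49-0.55); truth 0.5
EMRR of x on excess cvd mortality: 2.03 (95% CI 1.78-2.31); truth 2.0
shared period EMRR: 0.80 (0.76-0.84); truth 0.8
LR test for cause-specific x: chi2=397.4, df=1, p=2.1e-88
```

Each estimate brackets its generating value, and the likelihood-ratio
test detects that `x` acts differently on the two components.
`examples/03_crude_probabilities.py` continues to the crude probabilities
of death — e.g. for a woman aged 70 at diagnosis with `x=1`, the
estimated probability of having died of the excess cvd component by 15
years is 0.119 (95% CI 0.112–0.127), against 0.227 for the remaining
excess component and 0.389 for background causes, with
`S + Σ Cr = 1` holding to ~1e-4.

The other examples cover building cause-stratified life tables from raw
counts (`01`), the cause-of-death misclassification sensitivity analysis
(`04`), and time-dependent effects (`05`).

A thin CLI mirrors the pipeline:

```sh
flexcess simulate --n 5000 --seed 42 --out cohort.csv --lifetable-out lt.csv
flexcess fit --data cohort.csv --lifetable lt.csv --config model.json --out fit.json
flexcess predict --model fit.json --lifetable lt.csv --profile profile.json --out curves.csv
flexcess sensitivity --counts counts.csv --out table.csv
```

Every CLI run writes a JSON manifest (input checksums, seed, version)
next to its outputs.

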