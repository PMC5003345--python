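# Methods

## The model

A cohort of AD patients is followed from the initial clinic visit (t = 0,
time in years) with annual PSMS reassessment until death, loss to
follow-up, or administrative censoring. Basic-ADL impairment is an
intermediate state between diagnosis and death, giving the classical
three-state illness-death structure: intact → impaired (intensity
`h_I(t)`), intact → dead (`h_D1(t)`), impaired → dead (`h_D2(t)`). All
three transitions are modelled as Cox proportional-hazards regressions on
the same baseline covariates (age, sex, race, education, baseline MMSE,
symptom duration, marital status, CVDE), sharing the time-since-baseline
clock (a Markov, clock-forward specification). The post-impairment death
model uses a left-truncated likelihood: a patient enters its risk set only
at impairment onset, implemented through `(start, stop]` counting-process
intervals with the risk-set rule `start < t ≤ stop`.

Two onset definitions are supported. The absolute rule (PSMS ≥ 7) admits
prevalent impairment: patients entering with a score above 6 occupy the
impaired state from t = 0 and contribute to the post-impairment death
model with `start = 0`, and to neither other transition. The relative rule
(rise ≥ 2 over own baseline) makes everyone intact at entry by
construction, so even high-scoring entrants remain in the intact-state
risk sets until they worsen.

Onset is dated at the first qualifying visit — impairment is only
observable at assessments — with a midpoint convention (`convention=
"midpoint"`) available for sensitivity analysis. A death with no
qualifying visit beforehand is treated as death without impairment;
impairment is never imputed into the gap between the last visit and death.
A death falling exactly on the qualifying visit is attributed to the
post-impairment transition (the onset is dated infinitesimally earlier) so
that every death lands in exactly one death model; this keeps the event
accounting exact: onset events = incident onsets, and pre- plus
post-impairment deaths = all deaths, on every run.

## Estimation

The Cox engine is written from first principles and is the package's core:
Newton–Raphson on the weighted partial likelihood with risk-set sums
assembled from suffix cumulative sums over rows sorted by `start` and
`stop` (O((n + d) log n) per iteration), step-halving on any likelihood
decrease (up to 10 halvings), convergence at |Δ log L| < 1e-9 within 50
iterations. Covariates are centred at their weighted mean internally;
coefficients are unchanged and the Breslow baseline cumulative hazard then
refers to the stored centring point, which predictions re-apply. Ties are
handled by the Breslow approximation by default — consistent with using
the Breslow baseline — with Efron available by option. Degenerate inputs
raise typed errors: no events; a covariate constant within every risk set
(named); coefficients passing |β| > 50 (monotone likelihood). The engine
is verified against an independently coded brute-force maximiser of the
same partial likelihood on small fixtures, and against lifelines on larger
ones (coefficients, SEs, robust SEs and log-likelihood agree to ~1e-6).

The proportional-hazards diagnostic is a score test of
`β(t) = β + θ·g(t)` with `g` the event-time rank, using the interaction
information after profiling out the main effects (per-covariate 1-df
chi-square plus a global test), alongside the Pearson correlation of the
Schoenfeld residuals with event rank. Simulated under the null it rejects
at 6–7% for n = 150; calibration is asserted within the 99% binomial band
around 5% over 200 replicates.

Loss to follow-up is addressed with the simple subject-level IPCW scheme:
a single logistic regression of the lost indicator on the nine baseline
covariates, weight `1 / (1 − p̂_lost)` attached to all of a patient's
rows. This is deliberately not the time-varying product-form IPCW (out of
scope); it corrects composition of the risk sets on average but not its
time path, a known simplification. Weights are capped at the 99th
percentile by default (configurable, logged); weights are always ≥ 1.
Because weighting invalidates the model-based variance (measured coverage
0.89–0.91), weighted fits should use the Lin–Wei sandwich covariance
(`robust=True`, clustered on patient), which restores nominal coverage
(0.946/0.958/0.953 per transition in the recovery study); the unweighted
default keeps the plain variance, matching how such analyses are usually
reported.

Conditional death-probability curves condition on the state occupied at
the start of observation: `F_k(t|z) = 1 − exp(−exp(β_k·(z − z̄))·H_0k(t))`
with k = D1 (intact) or D2 (impaired). These are state-conditional
predictions, not path-integrated Aalen–Johansen occupation probabilities
(a documented non-goal). Two support caveats follow from the construction:
the impaired-state baseline has no mass before the earliest onset in the
data unless prevalent cases seed it from t = 0, so under the relative
definition the impaired curve is flat near the origin; and late-time
increments of the intact-state baseline rest on small risk sets and are
noisy. The average-patient profile uses the published population means
(age 75.1, education 13.6, MMSE 19.0); covariates without a published
setting (race, marital status, CVDE, symptom duration) follow a
modal-category / population-mean policy (white, married, CVDE present,
3.9 years), configurable and logged with every prediction.

## The synthetic-data generator

`study_like_scenario()` defines the study conditions: baseline covariates
match the published marginals (age ~ N(75.1, 8.3) truncated to [39, 97];
education ~ N(13.6, 3.6) ≥ 0; MMSE ~ N(20.06, 7) truncated to [0, 30] and
rounded — the location is truncation-corrected so the realised mean is
19.0; symptom duration ~ gamma with mean 3.9, SD 2.3; female 68.8%, white
90.9%, married 60.8%, CVDE 62.2%; baseline PSMS a 44.5% point mass at 6,
else 7 + Poisson(3.5)). Transition intensities are Weibull — shape 1.2 /
scale 5.0 for onset, 1.1/18.0 and 1.1/8.0 for pre- and post-impairment
death — with true log-hazard-ratios set near the fitted values the
analysis itself produces on such cohorts (the one implausible sparse-cell
race estimate on post-impairment death is replaced by a moderate 0.3).
Dropout is logistic in age, education and MMSE (intercept −1.1), and
administrative censoring is drawn uniformly on 2–14 years to emulate
staggered enrolment under a common study end; a scalar horizon is the
degenerate case. Under these settings a cohort of 1029 yields ≈47% deaths,
≈16% lost, overall median survival ≈6.6 years (≈8 intact vs ≈5.3 impaired
at entry), and ≈50% incident impairment among the baseline-intact —
matching the population the analysis is designed for. The loss fraction in
the dedicated dropout-bias scenario is set higher (≈24%) so the
dropout-induced component of bias is well separated from Monte-Carlo
noise.

Impairment is generated as an *assessed* state. A latent progression time
drawn from `h_I` determines which annual visit first shows a qualifying
score, and the death hazard switches from `h_D1` to `h_D2` at that visit.
Had the switch occurred at the continuous latent time instead, deaths
landing between latent progression and the next visit would follow the
impaired-state hazard while being observed as never-impaired, and no
estimator working from visit data could recover the transition effects —
the assessed-state construction makes the generative process exactly the
model class the estimator fits, which is the right design for validating
an estimator. PSMS trajectories are written backwards from the onset
visit: flat at baseline before it, `max(7, baseline + 2)` at it (so both
definitions trigger together), then worsening one point per visit.
Patients impaired at entry keep a flat trajectory, so the relative
definition never fires for them; this is the mechanism that makes the two
definitions diverge (a rise of ≥ 2 while staying ≤ 6 being impossible with
a floor of 6). A consequence is that relative-definition fits on the
default scenario mix prevalent-impaired mortality into the "intact" state,
so ground-truth recovery is checked under the absolute definition (and the
relative-definition machinery on an all-intact-at-entry variant).

Per-patient randomness comes from an independent child stream of the
scenario seed keyed by patient index, so draws are order-independent and
cohorts are bit-reproducible.

## Problem sizes and numerical choices

The recovery study runs 100 replicates of n = 2000 (about two minutes on
one core): every true log-HR is recovered within 3 Monte-Carlo SEs and
robust-CI coverage is nominal, with the [0.92, 0.97] band applied to each
transition's mean coverage across its eight coefficients — at 100
replicates the per-coefficient binomial noise (SD ≈ 0.022) is wider than
the band, so roughly four of 24 individual coverages would fall outside it
even for an exactly calibrated method. The IPCW comparison uses 200
replicates of n = 1000; the diagnostic calibration 200 replicates of
n = 150; the closed-form curve check n = 5000 (sup-norm < 0.03 against the
exponential CDF). Onset-time discretisation to annual visits deforms the
onset-transition time scale slightly; with visit-date jitter of SD 0.1
years this stays within Monte-Carlo noise at these sizes.

## Limitations

* The generator does not emulate longitudinal MMSE decline (only baseline
  MMSE enters any model), item-level PSMS structure, or dependence between
  baseline impairment status and the other covariates — so the descriptive
  table's between-group covariate contrasts are null in synthetic data
  even though the real population shows them.
* Subject-level IPCW with a single cross-sectional dropout model cannot
  correct censoring whose dependence on covariates changes over time; no
  stabilised or pooled-logistic weights are provided.
* No frailty, stratification, or estimated time-varying coefficients
  beyond the Schoenfeld diagnostic; no Aalen–Johansen occupation
  probabilities or competing-risk cumulative incidences.
* Passing tests on synthetic cohorts demonstrate correctness of the
  estimators under the stated generative assumptions (proportional
  hazards, Markov time scale, assessment-dated onset, covariate-driven
  dropout), not robustness to their violation in real clinic data.
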