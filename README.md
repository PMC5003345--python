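# adlsurv

Survival modelling of cognitively-driven basic-ADL impairment in
Alzheimer's disease cohorts.

Patients with AD differ in whether they pass through a stage of impaired
basic activities of daily living (feeding, dressing, grooming, ambulation,
bathing, continence) before death. `adlsurv` implements the full analysis
chain for asking what that intermediate state contributes to mortality
risk, on longitudinal clinic data with annual Physical Self-Maintenance
Scale (PSMS) assessments:

* **Impairment detection** from serial PSMS scores under two complementary
  rules — an absolute one (total score ≥ 7; 6 is fully intact) and a
  relative one (rise of ≥ 2 points over the patient's own baseline) — and
  expansion of each patient into `(start, stop]` counting-process episodes
  with a time-dependent impairment indicator.
* **A from-scratch weighted Cox engine**: Newton–Raphson maximisation of
  the partial likelihood over counting-process rows with delayed entry
  (risk set `start < t ≤ stop`), Breslow or Efron ties, step-halving,
  model-based and Lin–Wei robust (sandwich) covariance, Breslow cumulative
  baseline hazard, Schoenfeld-residual proportional-hazards diagnostics,
  Kaplan–Meier curves and the log-rank test.
* **Inverse-probability-of-censoring weights (IPCW)**: a logistic model of
  loss to follow-up on nine baseline covariates gives each patient the
  fixed weight `1 / (1 − p̂_lost)`, capped at a configurable quantile.
* **The three-state illness-death model** (intact → impaired → dead,
  intact → dead): transition-specific Cox models `h_I`, `h_D1`, `h_D2`, the
  post-impairment death model fitted with a left-truncated likelihood so
  patients enter its risk set at impairment onset, all on one
  time-since-first-visit clock. Conditional death probabilities for a
  covariate profile z in state k follow
  `F_k(t | z) = 1 − exp(−exp(β_k·(z − z̄)) · H_0k(t))`.
* **A synthetic-cohort generator** that emulates the target population —
  published baseline marginals, Weibull proportional-hazards transition
  intensities, annual visits as the only window onto onset,
  covariate-dependent dropout, staggered administrative censoring — with
  full ground truth, so every stage of the pipeline is testable against
  known parameters.

## Worked example

```bash
python analysis/01_simulate_cohort.py
python analysis/02_descriptives.py
python analysis/03_cox_models.py
python analysis/04_multistate.py
python analysis/05_death_probability_curves.py
```

The first script draws the study-like cohort (n = 1029) and prints its
composition; on the default seed:

```
cohort: 1029 patients, 4230 visits
  baseline ADL-impaired : 56.7%
  died under follow-up  : 50.7%
  lost to follow-up     : 15.4%
```

`03_cox_models.py` fits the IPCW-weighted death models and prints, for the
same cohort:

```
baseline model: HR per baseline PSMS point = 1.06, male HR = 1.72
time-dependent impairment (def1_psms_ge7): HR 2.25 (1.78, 2.83)
time-dependent impairment (def2_delta_ge2): HR 1.29 (1.03, 1.63)
```

i.e. each additional point of baseline ADL impairment raises the death
hazard by ~6%, and *developing* impairment during follow-up more than
doubles it under the absolute definition. `05_death_probability_curves.py`
turns the multistate fits into 6-year conditional death probabilities for
the average patient (age 75.1, 13.6 years of education, baseline MMSE 19):

```
state                  impaired  intact
definition     sex
def1_psms_ge7  female      42.3    16.6
               male        61.7    32.4
```

A man already impaired at observation start has a 62% predicted chance of
dying within six years versus 32% if intact; impairment status separates
the curves more strongly than sex does. All tables land under `results/`.

The same pipeline runs on real data from the shell: a long-format cohort
CSV (or a column-mapped wide XLSX via `adlsurv.read_cohort_xlsx`) goes
through

```bash
adlsurv analyze --input cohort.csv --outdir results/run
```

which emits the descriptive table, all Cox and multistate hazard-ratio
tables, the predicted curves, and a run log echoing every setting
(tie rule, IPCW cap, onset convention, profile policy, seed) with a config
hash stamped on each artifact.

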