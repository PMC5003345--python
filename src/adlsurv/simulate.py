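"""Synthetic AD-cohort generator with full ground truth.

Emulates the statistical structure the analysis pipeline assumes: baseline
covariates drawn to match the study population's marginals, a latent
illness-death process (intact -> impaired -> dead, intact -> dead) with
Weibull proportional-hazards transition intensities on a shared
time-since-baseline clock, annual follow-up visits at which PSMS is the
only window onto the latent onset, covariate-dependent loss to follow-up,
and staggered administrative censoring.

Observation model
-----------------
Impairment is an *assessed* state: a latent progression time drawn from the
onset intensity h_I determines which annual visit first shows a qualifying
PSMS score, and the death hazard switches from h_D1 to h_D2 at that visit.
(Switching instead at the continuous latent time would make deaths landing
between latent progression and the next visit follow h_D2 while being coded
never-impaired, so no estimator working from visit data could recover the
transition effects; tying the state to the assessment makes the generative
process exactly the illness-death model the pipeline fits.)

The generator writes PSMS scores that trigger *both* impairment definitions
exactly at the qualifying visit (score max(7, baseline + 2), then worsening
by one point per year). Patients impaired at baseline keep a flat PSMS
trajectory, so the relative (delta >= 2) definition never fires for them —
which is precisely how the two definitions are made to diverge, since a
delta >= 2 while staying <= 6 is impossible with a floor of 6. Patients who
die or are censored before the first qualifying visit are observed (and
simulated) as never impaired.

Per-patient randomness comes from an independent child of the scenario seed
keyed by patient index, so draws are order-independent and a scenario is
byte-reproducible for a given seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
import numpy as np
import pandas as pd

from .cohort import Cohort, MODEL_COVARIATES

#: Reference values used to centre covariates inside the simulated hazards,
#: so baseline intensities refer to an average patient.
REFERENCE_MEANS = {
    "age": 75.1, "male": 0.312, "nonwhite": 0.091, "education": 13.6,
    "mmse0": 19.0, "symptom_duration": 3.9, "not_married": 0.392,
    "cvde": 0.622,
}


@dataclass(frozen=True)
class Weibull:
    """Weibull hazard with cumulative H(t) = (t / scale) ** shape."""

    shape: float
    scale: float

    def __post_init__(self):
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("Weibull shape and scale must be positive")

    def cumhaz(self, t):
        return (np.asarray(t, float) / self.scale) ** self.shape

    def inverse_cumhaz(self, h):
        return self.scale * np.asarray(h, float) ** (1.0 / self.shape)

    def draw(self, rng: np.random.Generator, eta: float,
             entry: float = 0.0) -> float:
        """Event time with hazard exp(eta) * h0(t), conditional on T > entry."""
        e = rng.exponential()
        return float(self.inverse_cumhaz(self.cumhaz(entry) + e / np.exp(eta)))

    def survival(self, t, eta: float = 0.0):
        return np.exp(-np.exp(eta) * self.cumhaz(t))


@dataclass
class SimScenario:
    """Full data-generating specification for one synthetic cohort."""

    n: int
    seed: int
    # covariate laws
    p_female: float = 0.688
    p_white: float = 0.909
    p_married: float = 0.608
    p_cvde: float = 0.622
    age_mean: float = 75.1
    age_sd: float = 8.3
    age_range: tuple[float, float] = (39.0, 97.0)
    education_mean: float = 13.6
    education_sd: float = 3.6
    education_range: tuple[float, float] = (0.0, 29.0)
    mmse_mean: float = 19.0
    mmse_sd: float = 7.0
    symptom_mean: float = 3.9
    symptom_sd: float = 2.3
    symptom_range: tuple[float, float] = (0.5, 18.0)
    p_baseline_intact: float = 0.445
    psms0_excess_mean: float = 3.5       # impaired baseline: 7 + Poisson(mean)
    # transition intensities (shared time-since-baseline clock)
    base_I: Weibull = field(default_factory=lambda: Weibull(1.2, 5.0))
    base_D1: Weibull = field(default_factory=lambda: Weibull(1.1, 18.0))
    base_D2: Weibull = field(default_factory=lambda: Weibull(1.1, 8.0))
    beta_I: dict = field(default_factory=dict)
    beta_D1: dict = field(default_factory=dict)
    beta_D2: dict = field(default_factory=dict)
    # observation process
    visit_interval: float = 1.0
    visit_jitter_sd: float = 0.1
    dropout_intercept: float = -np.inf    # -inf disables loss to follow-up
    dropout_coef: dict = field(default_factory=dict)
    admin_censor: tuple[float, float] = (2.0, 14.0)

    def __post_init__(self):
        for p in (self.p_female, self.p_white, self.p_married, self.p_cvde,
                  self.p_baseline_intact):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.admin_censor[0] > self.admin_censor[1] \
                or self.admin_censor[0] <= 0:
            raise ValueError("admin_censor window must be 0 < lo <= hi")
        if self.admin_censor[0] < self.visit_interval + 0.5:
            # guarantees at least one visit precedes any administrative
            # censoring, mirroring the >=1-follow-up-visit inclusion rule
            raise ValueError("admin_censor lower bound must exceed "
                             "visit_interval + 0.5")
        for b in (self.beta_I, self.beta_D1, self.beta_D2, self.dropout_coef):
            unknown = set(b) - set(MODEL_COVARIATES)
            if unknown:
                raise ValueError(f"unknown covariate(s) in effects: {unknown}")

    def beta_vector(self, which: str) -> pd.Series:
        b = {"I": self.beta_I, "D1": self.beta_D1, "D2": self.beta_D2}[which]
        return pd.Series({c: float(b.get(c, 0.0)) for c in MODEL_COVARIATES})

    def to_json(self) -> str:
        d = asdict(self)
        for k in ("base_I", "base_D1", "base_D2"):
            d[k] = asdict(getattr(self, k))
        return json.dumps(d, indent=1, default=float)

    @classmethod
    def from_json(cls, text: str) -> "SimScenario":
        d = json.loads(text)
        for k in ("base_I", "base_D1", "base_D2"):
            d[k] = Weibull(**d[k])
        for k in ("age_range", "education_range", "symptom_range",
                  "admin_censor"):
            d[k] = tuple(d[k])
        if d.get("dropout_intercept") is None:
            d["dropout_intercept"] = -np.inf
        return cls(**d)


@dataclass
class GroundTruth:
    """Latent quantities behind one simulated cohort."""

    scenario: SimScenario
    latent: pd.DataFrame        # per-patient latent times, path, risks
    warnings: list[str] = field(default_factory=list)

    def true_beta(self, which: str) -> pd.Series:
        return self.scenario.beta_vector(which)

    def to_json(self) -> str:
        return json.dumps({
            "scenario": json.loads(self.scenario.to_json()),
            "latent": self.latent.to_dict(orient="list"),
            "warnings": self.warnings,
        }, indent=1, default=float)


def _truncated_normal(rng, mean, sd, lo, hi):
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return x
    return float(np.clip(x, lo, hi))


def _draw_covariates(rng: np.random.Generator, s: SimScenario) -> dict:
    sex = "male" if rng.random() >= s.p_female else "female"
    race = "white" if rng.random() < s.p_white else "nonwhite"
    marital = "married" if rng.random() < s.p_married else "not_married"
    cvde = bool(rng.random() < s.p_cvde)
    age = _truncated_normal(rng, s.age_mean, s.age_sd, *s.age_range)
    edu = round(_truncated_normal(rng, s.education_mean, s.education_sd,
                                  *s.education_range), 1)
    mmse0 = int(round(_truncated_normal(rng, s.mmse_mean, s.mmse_sd, 0, 30)))
    sympt = float(np.clip(rng.gamma((s.symptom_mean / s.symptom_sd) ** 2,
                                    s.symptom_sd ** 2 / s.symptom_mean),
                          *s.symptom_range))
    if rng.random() < s.p_baseline_intact:
        psms0 = 6
    else:
        psms0 = int(min(7 + rng.poisson(s.psms0_excess_mean), 28))
    return {"age_at_baseline": round(age, 1), "sex": sex, "race": race,
            "education": edu, "marital": marital, "cvde": cvde,
            "symptom_duration": round(sympt, 1), "mmse0": mmse0,
            "psms0": psms0}


def _model_covariates(b: dict) -> dict:
    return {"age": b["age_at_baseline"],
            "male": 1.0 if b["sex"] == "male" else 0.0,
            "nonwhite": 1.0 if b["race"] == "nonwhite" else 0.0,
            "education": b["education"], "mmse0": float(b["mmse0"]),
            "symptom_duration": b["symptom_duration"],
            "not_married": 1.0 if b["marital"] == "not_married" else 0.0,
            "cvde": 1.0 if b["cvde"] else 0.0}


def simulate_cohort(s: SimScenario) -> tuple[Cohort, GroundTruth]:
    """Draw one cohort and its ground truth from a scenario.

    Same scenario (including seed) always yields an identical cohort.
    """
    base_rows, visit_rows, outcome_rows, latent_rows = [], [], [], []
    ref = pd.Series(REFERENCE_MEANS)
    betas = {k: s.beta_vector(k) for k in ("I", "D1", "D2")}
    drop_coef = pd.Series({c: float(s.dropout_coef.get(c, 0.0))
                           for c in MODEL_COVARIATES})
    for i in range(s.n):
        rng = np.random.default_rng([int(s.seed), i])
        pid = f"P{i:05d}"
        b = _draw_covariates(rng, s)
        z = pd.Series(_model_covariates(b))
        zc = z - ref
        eta = {k: float(betas[k] @ zc) for k in ("I", "D1", "D2")}

        # administrative horizon and the full visit schedule up to it
        c_admin = rng.uniform(*s.admin_censor)
        schedule, j = [], 1
        while True:
            jitter = float(np.clip(rng.normal(0.0, s.visit_jitter_sd),
                                   -0.45, 0.45)) if s.visit_jitter_sd else 0.0
            t_v = round(j * s.visit_interval + jitter, 4)
            if t_v >= c_admin:
                break
            schedule.append(t_v)
            j += 1

        # illness-death path; the h_D1 -> h_D2 switch happens at the first
        # visit showing a qualifying score (the assessed onset)
        if b["psms0"] >= 7:  # impaired at entry: death hazard h_D2 from 0
            t_onset_latent, switch = 0.0, 0.0
            t_death = s.base_D2.draw(rng, eta["D2"])
            path = "baseline_impaired"
        else:
            t_i = s.base_I.draw(rng, eta["I"])
            t_onset_latent = float(t_i)
            hits = [t for t in schedule if t >= t_i]
            switch = hits[0] if hits else np.inf
            t_d1 = s.base_D1.draw(rng, eta["D1"])
            if t_d1 <= switch:
                switch, t_death, path = np.inf, t_d1, "death_intact"
            else:
                t_death = s.base_D2.draw(rng, eta["D2"], entry=switch)
                path = "death_after_onset"

        # loss to follow-up and end of observation
        p_lost = 1.0 / (1.0 + np.exp(-(s.dropout_intercept + drop_coef @ zc)))
        t_lost = rng.uniform(0.0, c_admin) if rng.random() < p_lost else np.inf
        end = min(t_death, t_lost, c_admin)
        status = ("dead" if end == t_death
                  else "lost" if end == t_lost else "censored_admin")
        end = max(round(float(end), 4), 1e-4)  # follow-up never ends at t=0

        times = [t for t in schedule if t < end]
        observed_onset = (switch if path == "death_after_onset"
                          and switch < end else None)
        for t_v in times:
            if path == "baseline_impaired" or observed_onset is None \
                    or t_v < observed_onset:
                psms = b["psms0"]
            else:
                k = sum(1 for t in times if observed_onset <= t <= t_v) - 1
                psms = min(max(7, b["psms0"] + 2) + k, 30)
            visit_rows.append({"patient_id": pid, "visit_time": t_v,
                               "psms": psms, "mmse": np.nan})

        base_rows.append({"patient_id": pid, **b})
        outcome_rows.append({"patient_id": pid, "followup_end": end,
                             "status": status})
        latent_rows.append({
            "patient_id": pid, "path": path,
            "t_onset_latent": t_onset_latent,
            "t_switch": None if np.isinf(switch) else float(switch),
            "t_death_latent": float(t_death), "t_admin": float(c_admin),
            "p_lost": float(p_lost),
            "lost": status == "lost", "observed_onset": observed_onset,
            "eta_I": eta["I"], "eta_D1": eta["D1"], "eta_D2": eta["D2"],
        })

    cohort = Cohort(pd.DataFrame(base_rows), pd.DataFrame(visit_rows),
                    pd.DataFrame(outcome_rows))
    latent = pd.DataFrame(latent_rows)
    warnings = []
    n_dead = int((cohort.outcomes["status"] == "dead").sum())
    if n_dead == 0:
        warnings.append("scenario produced zero observed deaths")
    return cohort, GroundTruth(s, latent, warnings)


# ---------------------------------------------------------------------------
# Preset scenarios


def study_like_scenario(n: int = 1029, seed: int = 0) -> SimScenario:
    """Scenario matching the study population's baseline marginals.

    Covariate laws reproduce the published population marginals; the
    transition log-hazard-ratios sit near the published multistate
    estimates (the implausibly large sparse-cell race effect on
    post-impairment death is replaced by a moderate 0.3); intensities and
    the censoring mix are calibrated so that roughly half of
    baseline-intact patients develop impairment under observation, just
    under half of the cohort dies, and about one in six is lost.
    """
    return SimScenario(
        n=n, seed=seed,
        beta_I={"age": 0.01, "male": -0.03, "nonwhite": 0.04,
                "education": 0.02, "mmse0": -0.07, "symptom_duration": -0.01,
                "not_married": -0.10, "cvde": 0.07},
        beta_D1={"age": 0.05, "male": 0.73, "nonwhite": 0.31,
                 "education": -0.05, "mmse0": -0.09,
                 "symptom_duration": -0.03, "not_married": -0.36,
                 "cvde": -0.53},
        beta_D2={"age": 0.01, "male": 0.65, "nonwhite": 0.30,
                 "education": -0.01, "mmse0": -0.06,
                 "symptom_duration": 0.02, "not_married": 0.62,
                 "cvde": 0.31},
        dropout_intercept=-1.1,
        mmse_mean=20.06,   # pre-truncation location giving realized mean 19.0
        dropout_coef={"age": 0.02, "education": -0.03, "mmse0": -0.01},
    )


def constant_intensity_scenario(n: int = 5000, seed: int = 0,
                                rate_I: float = 0.12, rate_D1: float = 0.08,
                                rate_D2: float = 0.18,
                                horizon: float = 10.0) -> SimScenario:
    """All effects zero, exponential intensities, no dropout.

    Under this scenario every transition hazard is constant, so the
    conditional probability of death from either state has the closed form
    1 - exp(-rate * t) against which fitted curves can be checked.
    """
    return SimScenario(
        n=n, seed=seed,
        base_I=Weibull(1.0, 1.0 / rate_I), base_D1=Weibull(1.0, 1.0 / rate_D1),
        base_D2=Weibull(1.0, 1.0 / rate_D2),
        admin_censor=(horizon, horizon), visit_jitter_sd=0.05,
    )


def dropout_bias_scenario(n: int = 1000, seed: int = 0,
                          age_logit_slope: float = 0.05) -> SimScenario:
    """Informative loss to follow-up driven by age.

    Death depends strongly on age (log-HR 0.10/yr) and on sex (log-HR 0.7
    for men, the coefficient of interest); the probability of being lost
    rises with age (logit slope ``age_logit_slope`` per year). A death
    model that omits age is then biased by the age-selective censoring, and
    inverse-probability-of-censoring weighting — whose logistic model does
    see age — should remove part of that bias. Impairment is effectively
    switched off so the death model is a plain survival fit.
    """
    return SimScenario(
        n=n, seed=seed,
        base_I=Weibull(1.0, 1e6),                  # nobody becomes impaired
        base_D1=Weibull(1.0, 9.0),                 # ~0.11/yr at reference
        base_D2=Weibull(1.0, 9.0),
        beta_D1={"age": 0.10, "male": 0.7},
        p_baseline_intact=1.0,                     # everyone starts intact
        dropout_intercept=-0.3,
        dropout_coef={"age": age_logit_slope},
        admin_censor=(10.0, 10.0),
    )
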