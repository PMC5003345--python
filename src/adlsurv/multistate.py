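"""Three-state illness-death model: intact -> impaired -> dead, intact -> dead.

Three transition-specific Cox models share one clock (years since the
initial visit, a Markov / clock-forward time scale):

* ``fit_I``   — hazard of basic-ADL impairment onset; death and censoring
  censor this transition.
* ``fit_D1``  — hazard of death while never-yet-impaired; impairment onset
  censors it.
* ``fit_D2``  — hazard of death after impairment, fitted with a
  left-truncated likelihood: patients enter the risk set at their onset
  time (at t=0 if already impaired at baseline under the absolute
  definition).

The fitted transition hazards combine into conditional death-probability
curves for covariate profiles: for a patient in state k at the start of
observation, P(dead by t) = 1 - exp(-exp(beta_k . (z - zbar)) * H0k(t))
with H0k the Breslow cumulative baseline of that transition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort, MODEL_COVARIATES
from .impairment import ImpairmentDefinition, OnsetResult, onsets_for_cohort
from .survival import CoxFit, EstimationError, fit_cox


class EmptyTransitionError(EstimationError):
    """A transition has no events, so its hazard cannot be estimated."""


#: Default covariates of every transition model (no baseline PSMS: the
#: impairment state itself carries that information).
TRANSITION_COVARIATES = list(MODEL_COVARIATES)


@dataclass
class MultistateFit:
    fit_I: CoxFit | None
    fit_D1: CoxFit | None
    fit_D2: CoxFit | None
    definition: ImpairmentDefinition
    covariates: list[str]
    n_onsets: int           # incident (post-baseline) onsets
    n_deaths: int
    n_baseline_impaired: int
    weighted: bool
    gaps: list[str] = field(default_factory=list)

    @property
    def transitions(self) -> dict[str, CoxFit | None]:
        return {"impairment": self.fit_I, "death_pre_impairment": self.fit_D1,
                "death_post_impairment": self.fit_D2}

    def event_accounting(self) -> dict[str, int]:
        """Event counts per transition; D1 + D2 deaths must equal deaths."""
        return {k: (0 if f is None else f.n_events)
                for k, f in self.transitions.items()}

    def hazard_ratio_table(self) -> pd.DataFrame:
        """Long-format HR table: one row per transition x covariate."""
        rows = []
        for name, f in self.transitions.items():
            if f is None:
                continue
            s = f.summary()
            for cov, r in s.iterrows():
                rows.append({"transition": name, "covariate": cov,
                             "coef": r["coef"], "se": r["se"], "hr": r["hr"],
                             "hr_lo": r["hr_lo"], "hr_hi": r["hr_hi"],
                             "p": r["p"]})
        return pd.DataFrame(rows)


def _transition_rows(cohort: Cohort, onsets: dict[str, OnsetResult],
                     covariates: list[str], weights: pd.Series | None):
    """Counting-process rows for the three transitions.

    A death occurring exactly at the qualifying visit is attributed to the
    post-impairment transition via an onset nudged infinitesimally earlier,
    so that every death lands in exactly one death model.
    """
    X = cohort.design_matrix(covariates)
    outcomes = cohort.outcomes.set_index("patient_id")
    recs_I, recs_D1, recs_D2 = [], [], []
    n_onsets = n_deaths = n_base_imp = 0
    for pid in cohort.patient_ids:
        o = onsets[pid]
        out = outcomes.loc[pid]
        end = float(out["followup_end"])
        died = out["status"] == "dead"
        n_deaths += int(died)
        w = float(weights.loc[pid]) if weights is not None else 1.0
        cov = {c: X.loc[pid, c] for c in covariates}
        base = {"patient_id": pid, "weight": w, **cov}
        if o.baseline_impaired:
            n_base_imp += 1
            if end > 0:
                recs_D2.append({**base, "start": 0.0, "stop": end,
                                "event": int(died)})
            continue
        t_star = o.onset_time
        if t_star is not None and t_star >= end:
            # qualifying visit at the very end of follow-up
            t_star = end - 1e-9 * max(1.0, end) if died else end
        if t_star is None:
            if end > 0:
                recs_I.append({**base, "start": 0.0, "stop": end, "event": 0})
                recs_D1.append({**base, "start": 0.0, "stop": end,
                                "event": int(died)})
        else:
            n_onsets += 1
            recs_I.append({**base, "start": 0.0, "stop": t_star, "event": 1})
            recs_D1.append({**base, "start": 0.0, "stop": t_star, "event": 0})
            if end > t_star:
                recs_D2.append({**base, "start": t_star, "stop": end,
                                "event": int(died)})
    cols = ["patient_id", "start", "stop", "event", "weight"] + covariates
    frame = lambda recs: pd.DataFrame(recs, columns=cols)
    return (frame(recs_I), frame(recs_D1), frame(recs_D2),
            n_onsets, n_deaths, n_base_imp)


def fit_multistate(cohort: Cohort, definition: ImpairmentDefinition | str,
                   weights: pd.Series | None = None,
                   covariates: list[str] | None = None,
                   convention: str = "visit", ties: str = "breslow",
                   robust: bool = False,
                   allow_partial: bool = False) -> MultistateFit:
    """Fit the three transition-specific Cox models.

    Under the absolute definition, patients impaired at baseline enter the
    post-impairment death model at t=0 and contribute to neither the onset
    nor the pre-impairment death model; under the relative definition every
    patient starts intact. ``weights`` are fixed subject-level weights
    (e.g. from :mod:`adlsurv.ipcw`).

    A transition without any event raises :class:`EmptyTransitionError`
    naming it, unless ``allow_partial`` is set, in which case that fit is
    None and the transition name is recorded in ``gaps``.
    """
    definition = ImpairmentDefinition.parse(definition)
    covariates = list(covariates or TRANSITION_COVARIATES)
    onsets = onsets_for_cohort(cohort, definition, convention)
    rows_I, rows_D1, rows_D2, n_on, n_dead, n_bi = _transition_rows(
        cohort, onsets, covariates, weights)
    fits: dict[str, CoxFit | None] = {}
    gaps: list[str] = []
    for name, rows in (("impairment", rows_I),
                       ("death_pre_impairment", rows_D1),
                       ("death_post_impairment", rows_D2)):
        if len(rows) == 0 or rows["event"].sum() == 0:
            msg = (f"transition {name!r} has no events"
                   + (" (nobody developed impairment)" if name !=
                      "death_pre_impairment" and n_on + n_bi == 0 else ""))
            if allow_partial:
                fits[name] = None
                gaps.append(name)
                continue
            raise EmptyTransitionError(msg)
        fits[name] = fit_cox(rows, covariates, ties=ties, robust=robust)
    ms = MultistateFit(fits["impairment"], fits["death_pre_impairment"],
                       fits["death_post_impairment"], definition, covariates,
                       n_on, n_dead, n_bi, weights is not None, gaps)
    acct = ms.event_accounting()
    if not gaps:
        assert acct["death_pre_impairment"] + acct["death_post_impairment"] \
            == n_dead, "death accounting violated"
        assert acct["impairment"] == n_on, "onset accounting violated"
    return ms


# ---------------------------------------------------------------------------
# Profiles and predicted conditional death probabilities


#: Average-patient profile reported with the study population:
#: age 75.1, 13.6 years of education, baseline MMSE 19.0; remaining
#: covariates set by the modal-category / cohort-mean policy.
DEFAULT_PROFILE = {
    "age": 75.1, "education": 13.6, "mmse0": 19.0,
    "male": 0.0, "nonwhite": 0.0, "not_married": 0.0, "cvde": 1.0,
    "symptom_duration": 3.9,
}


def average_profile(cohort: Cohort | None = None, **overrides) -> pd.Series:
    """Average-patient covariate profile.

    Continuous covariates default to the study-population means; the
    unreported ones (race, marital status, CVDE, symptom duration) follow
    the modal-category / cohort-mean policy, computed from ``cohort`` when
    one is supplied. Keyword overrides always win.
    """
    prof = dict(DEFAULT_PROFILE)
    if cohort is not None:
        X = cohort.design_matrix(MODEL_COVARIATES + ["psms0"])
        prof.update({
            "nonwhite": float(round(X["nonwhite"].mean())),
            "not_married": float(round(X["not_married"].mean())),
            "cvde": float(round(X["cvde"].mean())),
            "symptom_duration": float(X["symptom_duration"].mean()),
        })
    prof.update(overrides)
    return pd.Series(prof)


def conditional_death_probability(ms: MultistateFit, profile: pd.Series | dict,
                                  state: str, grid) -> pd.DataFrame:
    """P(dead by t | state at observation start, covariates = profile).

    ``state`` is ``"intact"`` (uses the pre-impairment death transition) or
    ``"impaired"`` (post-impairment transition, whose baseline hazard was
    estimated under left truncation at onset). The curve is non-decreasing
    and within [0, 1]; it is 0 at t = 0.
    """
    if state not in ("intact", "impaired"):
        raise ValueError(f"state must be 'intact' or 'impaired', got {state!r}")
    fit = ms.fit_D1 if state == "intact" else ms.fit_D2
    if fit is None:
        raise EmptyTransitionError(f"no fitted death model for state {state!r}")
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    if np.any(grid < 0):
        raise ValueError("prediction times must be non-negative")
    lp = fit.linear_predictor(profile)
    H = fit.baseline_cumhaz(grid)
    prob = 1.0 - np.exp(-np.exp(lp) * np.atleast_1d(H))
    return pd.DataFrame({"time": grid, "prob_death": prob})


def figure2_curves(ms_by_definition: dict[str, MultistateFit],
                   profile_base: pd.Series | dict | None = None,
                   horizon: float = 6.0, step: float = 0.05) -> pd.DataFrame:
    """Predicted conditional death-probability curves, sex x state.

    For each fitted definition, four curves over ``[0, horizon]`` for the
    average patient: {female, male} x {intact, impaired}. Returns a tidy
    frame (definition, sex, state, time, prob_death) ready for CSV export
    or plotting.
    """
    base = pd.Series(profile_base) if profile_base is not None \
        else average_profile()
    grid = np.round(np.arange(0.0, horizon + step / 2, step), 10)
    out = []
    for tag, ms in ms_by_definition.items():
        for sex, male in (("female", 0.0), ("male", 1.0)):
            prof = base.copy()
            prof["male"] = male
            for state in ("intact", "impaired"):
                cur = conditional_death_probability(ms, prof, state, grid)
                cur.insert(0, "definition", tag)
                cur.insert(1, "sex", sex)
                cur.insert(2, "state", state)
                out.append(cur)
    return pd.concat(out, ignore_index=True)
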