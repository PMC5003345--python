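"""Basic-ADL impairment onset from PSMS trajectories, and episode splitting.

Two complementary definitions of incident impairment are supported:

* ``def1_psms_ge7`` — absolute: the first post-baseline visit with a total
  PSMS score of 7 or more (6 means fully intact); a baseline score >= 7
  means the patient is impaired from entry.
* ``def2_delta_ge2`` — relative: the first visit whose PSMS exceeds the
  patient's own baseline score by 2 or more points; nobody is impaired at
  baseline under this definition, so even patients entering with a high
  score can still transition.

Onset is dated at the first qualifying visit (annual reassessments are the
only times impairment can be observed); a midpoint convention — halfway
between the last non-qualifying assessment and the qualifying one — is
available for sensitivity analyses.

``split_episodes``/``counting_process`` expand each patient into
``(start, stop]`` counting-process intervals carrying a time-dependent
impairment indicator, the format a Cox model with time-dependent covariates
consumes.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .cohort import Cohort, MODEL_COVARIATES


class ImpairmentDefinition(enum.Enum):
    DEF1_PSMS_GE7 = "def1_psms_ge7"
    DEF2_DELTA_GE2 = "def2_delta_ge2"

    @classmethod
    def parse(cls, tag: "ImpairmentDefinition | str") -> "ImpairmentDefinition":
        if isinstance(tag, cls):
            return tag
        for d in cls:
            if d.value == tag or d.name.lower() == str(tag).lower():
                return d
        raise ValueError(f"unknown impairment definition {tag!r}")


DEF1 = ImpairmentDefinition.DEF1_PSMS_GE7
DEF2 = ImpairmentDefinition.DEF2_DELTA_GE2


@dataclass(frozen=True)
class OnsetResult:
    """Impairment status of one patient under one definition.

    ``onset_time`` is None when impairment was never observed; it is 0.0
    only for patients impaired at baseline (possible under def1 only).
    """

    patient_id: str
    baseline_impaired: bool
    onset_time: float | None

    @property
    def ever_impaired(self) -> bool:
        return self.baseline_impaired or self.onset_time is not None


@dataclass(frozen=True)
class CountingProcessRow:
    patient_id: str
    start: float
    stop: float
    event: int
    impaired: int
    weight: float = 1.0


class EpisodeError(ValueError):
    """Onset and outcome are mutually inconsistent for a patient."""


def onset(visits: Iterable[tuple[float, int]] | pd.DataFrame, psms0: int,
          definition: ImpairmentDefinition | str,
          convention: str = "visit") -> OnsetResult | tuple[float | None, bool]:
    """Locate the impairment onset time in one patient's PSMS series.

    Parameters
    ----------
    visits
        ``(visit_time, psms)`` pairs sorted by time, or a DataFrame with
        ``visit_time``/``psms`` columns (a ``patient_id`` column, if present,
        labels the result).
    psms0
        Baseline PSMS total score (6-30).
    convention
        ``"visit"`` dates onset at the first qualifying visit; ``"midpoint"``
        halves the interval back to the previous assessment (baseline if the
        first visit qualifies).

    An empty series yields ``onset_time = None``: impairment that was never
    assessed is never imputed, even for patients who then died.
    """
    definition = ImpairmentDefinition.parse(definition)
    if convention not in ("visit", "midpoint"):
        raise ValueError(f"unknown onset convention {convention!r}")
    pid = ""
    if isinstance(visits, pd.DataFrame):
        if "patient_id" in visits.columns and len(visits):
            pid = str(visits["patient_id"].iloc[0])
        pairs = list(zip(visits["visit_time"].astype(float),
                         visits["psms"].astype(int)))
    else:
        pairs = [(float(t), int(s)) for t, s in visits]
    times = [t for t, _ in pairs]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError("visits must be sorted strictly by time")

    baseline_impaired = definition is DEF1 and psms0 >= 7
    qualifies = ((lambda s: s >= 7) if definition is DEF1
                 else (lambda s: s - psms0 >= 2))
    onset_time: float | None = None
    if baseline_impaired:
        onset_time = 0.0
    else:
        prev_t = 0.0
        for t, s in pairs:
            if qualifies(s):
                onset_time = t if convention == "visit" else (prev_t + t) / 2.0
                break
            prev_t = t
    return OnsetResult(pid, baseline_impaired, onset_time)


def split_episodes(outcome_end: float, status: str, o: OnsetResult,
                   weight: float = 1.0) -> list[CountingProcessRow]:
    """Expand one patient into disjoint contiguous ``(start, stop]`` rows.

    The impairment indicator switches from 0 to 1 at the onset time; the
    death indicator sits on the last row only. Patients impaired at baseline
    contribute a single impaired row covering all of follow-up.
    """
    event = int(status == "dead")
    end = float(outcome_end)
    t_star = o.onset_time
    if t_star is not None and t_star > end + 1e-12:
        raise EpisodeError(
            f"patient {o.patient_id!r}: onset at {t_star} after follow-up "
            f"end {end}")
    if t_star is None:
        return [CountingProcessRow(o.patient_id, 0.0, end, event,
                                   int(o.baseline_impaired), weight)]
    if t_star <= 0.0 or o.baseline_impaired:
        return [CountingProcessRow(o.patient_id, 0.0, end, event, 1, weight)]
    if t_star >= end:  # qualifying visit coincides with end of follow-up
        return [CountingProcessRow(o.patient_id, 0.0, end, event, 0, weight)]
    return [CountingProcessRow(o.patient_id, 0.0, t_star, 0, 0, weight),
            CountingProcessRow(o.patient_id, t_star, end, event, 1, weight)]


def onsets_for_cohort(cohort: Cohort, definition: ImpairmentDefinition | str,
                      convention: str = "visit") -> dict[str, OnsetResult]:
    """Onset results for every patient, keyed by patient_id."""
    definition = ImpairmentDefinition.parse(definition)
    psms0 = cohort.baselines.set_index("patient_id")["psms0"]
    out: dict[str, OnsetResult] = {}
    grouped = dict(tuple(cohort.visits.groupby("patient_id", sort=False)))
    for pid in cohort.patient_ids:
        grp = grouped.get(pid)
        pairs = ([] if grp is None
                 else list(zip(grp["visit_time"], grp["psms"])))
        res = onset(pairs, int(psms0.loc[pid]), definition, convention)
        out[pid] = OnsetResult(pid, res.baseline_impaired, res.onset_time)
    return out


def counting_process(cohort: Cohort, definition: ImpairmentDefinition | str,
                     covariates: list[str] | None = None,
                     weights: pd.Series | None = None,
                     convention: str = "visit",
                     include_baseline_impaired: bool = True) -> pd.DataFrame:
    """Counting-process table for a time-dependent-impairment death model.

    One or two rows per patient (pre-/post-onset), fixed baseline covariates
    replicated on every row, ``impaired`` switching at onset, and optional
    subject-level weights (e.g. inverse-probability-of-censoring weights).

    ``include_baseline_impaired=False`` restricts to patients intact at
    baseline (relevant under the absolute definition only).
    """
    covariates = list(covariates or MODEL_COVARIATES)
    X = cohort.design_matrix(covariates)
    onsets = onsets_for_cohort(cohort, definition, convention)
    outcomes = cohort.outcomes.set_index("patient_id")
    rows = []
    for pid in cohort.patient_ids:
        o = onsets[pid]
        if not include_baseline_impaired and o.baseline_impaired:
            continue
        out = outcomes.loc[pid]
        w = float(weights.loc[pid]) if weights is not None else 1.0
        for r in split_episodes(out["followup_end"], out["status"], o, w):
            rows.append({"patient_id": pid, "start": r.start, "stop": r.stop,
                         "event": r.event, "impaired": r.impaired,
                         "weight": r.weight,
                         **{c: X.loc[pid, c] for c in covariates}})
    df = pd.DataFrame(rows, columns=["patient_id", "start", "stop", "event",
                                     "impaired", "weight"] + covariates)
    return df[df["stop"] > df["start"]].reset_index(drop=True)
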