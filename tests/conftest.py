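import numpy as np
import pandas as pd
import pytest

from adlsurv.cohort import Cohort


def build_cohort(baselines, visits, outcomes) -> Cohort:
    """Assemble a Cohort from terse per-patient tuples.

    baselines: (pid, age, sex, race, edu, marital, cvde, sympt, mmse0, psms0)
    visits:    (pid, time, psms)
    outcomes:  (pid, end, status)
    """
    b = pd.DataFrame(baselines, columns=[
        "patient_id", "age_at_baseline", "sex", "race", "education",
        "marital", "cvde", "symptom_duration", "mmse0", "psms0"])
    v = pd.DataFrame(visits, columns=["patient_id", "visit_time", "psms"])
    v["mmse"] = np.nan
    o = pd.DataFrame(outcomes, columns=["patient_id", "followup_end",
                                        "status"])
    return Cohort(b, v, o)


@pytest.fixture
def small_cohort() -> Cohort:
    """Three patients, five visits: one incident onset then death, one
    baseline-impaired censored, one never-impaired lost to follow-up."""
    return build_cohort(
        baselines=[
            ("A", 70.0, "female", "white", 12.0, "married", True, 3.0, 24, 6),
            ("B", 80.0, "male", "nonwhite", 8.0, "not_married", False, 5.0,
             15, 9),
            ("C", 75.0, "female", "white", 16.0, "married", True, 2.0, 28, 6),
        ],
        visits=[("A", 1.0, 6), ("A", 2.0, 8),
                ("B", 1.0, 9), ("B", 2.0, 10),
                ("C", 1.0, 6)],
        outcomes=[("A", 2.5, "dead"), ("B", 4.0, "censored_admin"),
                  ("C", 3.0, "lost")],
    )
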