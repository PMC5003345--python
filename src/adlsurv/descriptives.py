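"""Baseline-characteristics table with two-group comparisons.

The classic opening table of a cohort study: continuous variables as
mean +/- SD (min, max) compared by Student's t test, categorical variables
as n (%) compared by the chi-square test, and median survival from the
product-limit curve compared by the log-rank test. The grouping is
baseline basic-ADL status (PSMS total 6 = intact, >= 7 = impaired).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort
from .survival import km_curve, logrank_test

CONTINUOUS = [
    ("age_at_baseline", "Age at baseline (years)"),
    ("education", "Formal education (years)"),
    ("symptom_duration", "Symptom duration (years)"),
    ("mmse0", "MMSE score at baseline"),
    ("psms0", "PSMS score at baseline"),
]
CATEGORICAL = [
    ("female", "Female, n (%)"),
    ("white", "White, n (%)"),
    ("married", "Married, n (%)"),
    ("death", "Death, n (%)"),
    ("cvde", "CVDE, n (%)"),
]


def _indicators(cohort: Cohort) -> pd.DataFrame:
    b = cohort.baselines.set_index("patient_id")
    o = cohort.outcomes.set_index("patient_id").loc[b.index]
    return pd.DataFrame({
        "female": (b["sex"] == "female").astype(int),
        "white": (b["race"] == "white").astype(int),
        "married": (b["marital"] == "married").astype(int),
        "death": (o["status"] == "dead").astype(int),
        "cvde": b["cvde"].astype(int),
        "age_at_baseline": b["age_at_baseline"],
        "education": b["education"],
        "symptom_duration": b["symptom_duration"],
        "mmse0": b["mmse0"].astype(float),
        "psms0": b["psms0"].astype(float),
        "followup_end": o["followup_end"],
        "group": (b["psms0"] >= 7).map({False: "intact", True: "impaired"}),
    })


def _cont_cell(x: pd.Series) -> str:
    if x.std(ddof=1) != x.std(ddof=1) or len(x) < 2:  # NaN guard
        return f"{x.mean():.1f}"
    return f"{x.mean():.1f} ± {x.std(ddof=1):.1f} ({x.min():.1f}, {x.max():.1f})"


def _cat_cell(x: pd.Series) -> str:
    return f"{int(x.sum())} ({100 * x.mean():.1f})"


def describe_groups(cohort: Cohort, grouping: str = "baseline_impairment",
                    ) -> pd.DataFrame:
    """Table-1-style report comparing baseline-intact vs -impaired patients.

    Returns one row per characteristic with formatted cells for the whole
    cohort and each group, plus the test used, its statistic, and p-value.
    Both groups must be non-empty.
    """
    if grouping != "baseline_impairment":
        raise ValueError(f"unknown grouping {grouping!r}")
    df = _indicators(cohort)
    g1 = df[df["group"] == "intact"]
    g2 = df[df["group"] == "impaired"]
    if len(g1) == 0 or len(g2) == 0:
        raise ValueError("grouping must split the cohort into two non-empty "
                         "groups")
    rows = []
    for col, label in CATEGORICAL:
        tab = np.array([[g1[col].sum(), len(g1) - g1[col].sum()],
                        [g2[col].sum(), len(g2) - g2[col].sum()]], float)
        if tab[:, 0].sum() in (0, len(df)):  # constant indicator
            chi2, p = 0.0, 1.0
        else:
            chi2, p, _, _ = stats.chi2_contingency(tab, correction=False)
        rows.append({"variable": label, "all": _cat_cell(df[col]),
                     "intact": _cat_cell(g1[col]),
                     "impaired": _cat_cell(g2[col]),
                     "test": "chi2", "statistic": float(chi2), "p": float(p)})
    for col, label in CONTINUOUS:
        if g1[col].nunique() <= 1 and g2[col].nunique() <= 1 \
                and g1[col].iloc[0] == g2[col].iloc[0]:
            t, p = 0.0, 1.0
        else:
            with np.errstate(all="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                t, p = stats.ttest_ind(g1[col], g2[col], equal_var=True)
        rows.append({"variable": label, "all": _cont_cell(df[col]),
                     "intact": _cont_cell(g1[col]),
                     "impaired": _cont_cell(g2[col]),
                     "test": "t", "statistic": float(t), "p": float(p)})
    lr = logrank_test((g1["followup_end"], g1["death"]),
                      (g2["followup_end"], g2["death"]))
    med = {name: km_curve(part["followup_end"], part["death"]).median
           for name, part in (("all", df), ("intact", g1), ("impaired", g2))}
    fmt = lambda m: "not reached" if m is None else f"{m:.1f}"
    rows.append({"variable": "Median survival from initial visit (years)",
                 "all": fmt(med["all"]), "intact": fmt(med["intact"]),
                 "impaired": fmt(med["impaired"]),
                 "test": "logrank", "statistic": lr["chi2"], "p": lr["p"]})
    return pd.DataFrame(rows)
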