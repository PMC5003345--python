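"""Longitudinal AD-cohort containers, readers/writers, and validation.

A cohort is one baseline row per patient (socio-demographics, comorbidity,
baseline MMSE/PSMS), a series of annual follow-up visits carrying PSMS (and
optionally MMSE) scores, and exactly one outcome row giving the end of
follow-up and how it ended (death, administrative censoring, or loss to
follow-up).

Time is measured in years since the patient's initial clinic visit, so every
baseline is at t = 0 and visit times are strictly positive.

The canonical on-disk format is a single long CSV with a ``record_type``
column taking the values ``baseline`` / ``visit`` / ``outcome``; a
column-mapped XLSX converter is provided for externally deposited
spreadsheets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

SEXES = ("female", "male")
RACES = ("white", "nonwhite")
MARITALS = ("married", "not_married")
STATUSES = ("dead", "censored_admin", "lost")

PSMS_MIN, PSMS_MAX = 6, 30
MMSE_MIN, MMSE_MAX = 0, 30

BASELINE_COLUMNS = [
    "patient_id", "age_at_baseline", "sex", "race", "education",
    "marital", "cvde", "symptom_duration", "mmse0", "psms0",
]
VISIT_COLUMNS = ["patient_id", "visit_time", "psms", "mmse"]
OUTCOME_COLUMNS = ["patient_id", "followup_end", "status"]

#: Model covariates in the order the hazard-ratio tables report them.
#: Indicator coding: male=1 (ref female), nonwhite=1 (ref white),
#: not_married=1 (ref married), cvde=1 (ref absent).
MODEL_COVARIATES = [
    "age", "male", "nonwhite", "education", "mmse0",
    "symptom_duration", "not_married", "cvde",
]


class SchemaError(ValueError):
    """A required column is missing or a categorical level is unknown."""


class IntegrityError(ValueError):
    """Rows contradict the cohort invariants (duplicates, negative times...)."""


@dataclass(frozen=True)
class Violation:
    """One validation failure, attributable to a patient and a rule."""

    patient_id: str
    rule: str
    message: str

    def to_dict(self) -> dict:
        return {"patient_id": self.patient_id, "rule": self.rule,
                "message": self.message}


@dataclass
class Cohort:
    """In-memory cohort: three aligned DataFrames keyed by ``patient_id``.

    ``baselines`` has one row per patient; ``visits`` zero or more rows per
    patient sorted by ``visit_time``; ``outcomes`` exactly one row per
    patient. Constructing a Cohort normalises dtypes and sort order so that
    input row order never affects downstream results.
    """

    baselines: pd.DataFrame
    visits: pd.DataFrame
    outcomes: pd.DataFrame

    def __post_init__(self) -> None:
        self.baselines = _normalise(self.baselines, BASELINE_COLUMNS, "baseline")
        self.visits = _normalise(self.visits, VISIT_COLUMNS, "visit")
        self.outcomes = _normalise(self.outcomes, OUTCOME_COLUMNS, "outcome")
        dup = self.visits.duplicated(["patient_id", "visit_time"])
        if dup.any():
            pid = self.visits.loc[dup, "patient_id"].iloc[0]
            raise IntegrityError(
                f"duplicate (patient_id, visit_time) rows, e.g. patient {pid!r}")
        if self.outcomes["patient_id"].duplicated().any():
            raise IntegrityError("more than one outcome row for a patient")
        if (self.visits["visit_time"] <= 0).any():
            pid = self.visits.loc[self.visits["visit_time"] <= 0,
                                  "patient_id"].iloc[0]
            raise IntegrityError(
                f"visit at or before baseline (visit_time <= 0) for {pid!r}")
        known = set(self.baselines["patient_id"])
        for frame, what in ((self.visits, "visit"), (self.outcomes, "outcome")):
            orphan = set(frame["patient_id"]) - known
            if orphan:
                raise IntegrityError(
                    f"{what} rows for unknown patient_id(s): {sorted(orphan)[:5]}")

    # -- convenience accessors -------------------------------------------

    @property
    def n(self) -> int:
        return len(self.baselines)

    @property
    def patient_ids(self) -> list[str]:
        return self.baselines["patient_id"].tolist()

    def visits_of(self, patient_id: str) -> pd.DataFrame:
        return self.visits[self.visits["patient_id"] == patient_id]

    def outcome_of(self, patient_id: str) -> pd.Series:
        return self.outcomes.set_index("patient_id").loc[patient_id]

    def design_matrix(self, covariates: Iterable[str] = MODEL_COVARIATES,
                      ) -> pd.DataFrame:
        """Numeric covariate matrix (one row per patient, baseline order).

        Categorical baseline fields are expanded to the indicator coding of
        :data:`MODEL_COVARIATES`; ``age`` is ``age_at_baseline`` and
        ``psms0``/``mmse0`` pass through.
        """
        b = self.baselines
        pool = pd.DataFrame({
            "age": b["age_at_baseline"].to_numpy(float),
            "male": (b["sex"] == "male").astype(float).to_numpy(),
            "nonwhite": (b["race"] == "nonwhite").astype(float).to_numpy(),
            "education": b["education"].to_numpy(float),
            "mmse0": b["mmse0"].to_numpy(float),
            "psms0": b["psms0"].to_numpy(float),
            "symptom_duration": b["symptom_duration"].to_numpy(float),
            "not_married": (b["marital"] == "not_married").astype(float).to_numpy(),
            "cvde": b["cvde"].astype(float).to_numpy(),
        }, index=b["patient_id"])
        missing = [c for c in covariates if c not in pool.columns]
        if missing:
            raise SchemaError(f"unknown covariate(s): {missing}")
        return pool[list(covariates)]


def _normalise(df: pd.DataFrame, columns: list[str], kind: str) -> pd.DataFrame:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{kind} table is missing column(s): {missing}")
    out = df[columns].copy()
    out["patient_id"] = out["patient_id"].astype(str)
    if kind == "baseline":
        for col in ("age_at_baseline", "education", "symptom_duration"):
            out[col] = out[col].astype(float)
        for col in ("mmse0", "psms0"):
            out[col] = out[col].astype(int)
        out["cvde"] = out["cvde"].astype(bool)
        for col, levels in (("sex", SEXES), ("race", RACES), ("marital", MARITALS)):
            out[col] = out[col].astype(str)
            bad = set(out[col]) - set(levels)
            if bad:
                raise SchemaError(f"unknown {col} level(s) {sorted(bad)}; "
                                  f"expected one of {levels}")
        out = out.sort_values("patient_id", kind="stable")
    elif kind == "visit":
        out["visit_time"] = out["visit_time"].astype(float)
        out["psms"] = out["psms"].astype(int)
        out["mmse"] = pd.to_numeric(out["mmse"], errors="coerce")
        out = out.sort_values(["patient_id", "visit_time"], kind="stable")
    else:
        out["followup_end"] = out["followup_end"].astype(float)
        out["status"] = out["status"].astype(str)
        bad = set(out["status"]) - set(STATUSES)
        if bad:
            raise SchemaError(f"unknown outcome status(es) {sorted(bad)}; "
                              f"expected one of {STATUSES}")
        out = out.sort_values("patient_id", kind="stable")
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Derived covariates


def derive_cvde(history: Mapping[str, bool] | set[str]) -> bool:
    """Cardiovascular disease equivalent per NCEP-ATP III composite rules.

    True iff the history contains myocardial infarction, congestive heart
    failure, stent placement, or diabetes mellitus — or any two of
    hypertension, hyperlipidemia, and current smoking.
    """
    if isinstance(history, set):
        flags = {k: True for k in history}
    else:
        flags = dict(history)
    known = {"mi", "chf", "stent", "dm", "htn", "lipid", "smoking"}
    unknown = set(flags) - known
    if unknown:
        raise SchemaError(f"unknown comorbidity flag(s): {sorted(unknown)}")
    get = lambda k: bool(flags.get(k, False))
    if any(get(k) for k in ("mi", "chf", "stent", "dm")):
        return True
    return sum(get(k) for k in ("htn", "lipid", "smoking")) >= 2


# ---------------------------------------------------------------------------
# I/O


def read_cohort(path: str | Path, dialect: str = "long_csv") -> Cohort:
    """Read a cohort from the canonical long CSV.

    The file carries a ``record_type`` column with values
    ``baseline``/``visit``/``outcome``; each record type uses its own subset
    of the remaining columns, with unused cells left empty.
    """
    if dialect != "long_csv":
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, comment="#", dtype={"patient_id": str})
    if "record_type" not in df.columns:
        raise SchemaError("cohort CSV is missing column(s): ['record_type']")
    parts = {}
    for kind, cols in (("baseline", BASELINE_COLUMNS), ("visit", VISIT_COLUMNS),
                       ("outcome", OUTCOME_COLUMNS)):
        sub = df[df["record_type"] == kind]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise SchemaError(f"{kind} table is missing column(s): {missing}")
        parts[kind] = sub[cols]
    return Cohort(parts["baseline"], parts["visit"], parts["outcome"])


def write_cohort(cohort: Cohort, path: str | Path,
                 header_comment: str | None = None) -> Path:
    """Write the canonical long CSV; round-trips losslessly via read_cohort."""
    path = Path(path)
    b = cohort.baselines.copy()
    v = cohort.visits.copy()
    o = cohort.outcomes.copy()
    b.insert(0, "record_type", "baseline")
    v.insert(0, "record_type", "visit")
    o.insert(0, "record_type", "outcome")
    long = pd.concat([b, v, o], ignore_index=True)
    cols = ["record_type"] + BASELINE_COLUMNS + [
        c for c in VISIT_COLUMNS + OUTCOME_COLUMNS if c not in BASELINE_COLUMNS]
    long = long.reindex(columns=cols)
    long["cvde"] = long["cvde"].map({True: 1, False: 0})
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        long.to_csv(fh, index=False)
    return path


#: Default column mapping for a wide per-patient spreadsheet: one row per
#: patient, visit PSMS scores in columns ``psms_y1..psms_yK`` (years 1..K).
DEFAULT_XLSX_MAP: dict = {
    "patient_id": "patient_id",
    "age_at_baseline": "age_at_baseline",
    "sex": "sex",
    "race": "race",
    "education": "education",
    "marital": "marital",
    "cvde": "cvde",
    "symptom_duration": "symptom_duration",
    "mmse0": "mmse0",
    "psms0": "psms0",
    "followup_end": "followup_end",
    "status": "status",
    "visit_prefix": "psms_y",
}


def read_cohort_xlsx(path: str | Path, column_map: Mapping[str, str] | None = None,
                     sheet: int | str = 0) -> Cohort:
    """Convert a wide deposited spreadsheet to a :class:`Cohort`.

    The mapping is configurable because deposited files name columns
    idiosyncratically; per-visit PSMS columns are located by ``visit_prefix``
    (``<prefix>1``, ``<prefix>2``, ... = annual visits), with empty cells
    meaning no visit that year.
    """
    cmap = dict(DEFAULT_XLSX_MAP)
    if column_map:
        cmap.update(column_map)
    wide = pd.read_excel(Path(path), sheet_name=sheet)
    missing = [src for key, src in cmap.items()
               if key != "visit_prefix" and src not in wide.columns]
    if missing:
        raise SchemaError(f"spreadsheet is missing column(s): {missing}")
    base = pd.DataFrame({k: wide[cmap[k]] for k in BASELINE_COLUMNS})
    out = pd.DataFrame({k: wide[cmap[k]] for k in OUTCOME_COLUMNS})
    prefix = cmap["visit_prefix"]
    visit_cols = sorted((c for c in wide.columns if str(c).startswith(prefix)),
                        key=lambda c: int(str(c)[len(prefix):]))
    records = []
    for _, row in wide.iterrows():
        for c in visit_cols:
            if pd.notna(row[c]):
                records.append({"patient_id": row[cmap["patient_id"]],
                                "visit_time": float(str(c)[len(prefix):]),
                                "psms": int(row[c]), "mmse": np.nan})
    visits = pd.DataFrame(records, columns=VISIT_COLUMNS)
    return Cohort(base, visits, out)


# ---------------------------------------------------------------------------
# Validation


def validate_cohort(cohort: Cohort) -> list[Violation]:
    """Check every type invariant; reports violations instead of raising.

    Returns an empty list iff the cohort is internally consistent: scores in
    range, non-negative durations, strictly increasing visit times, one
    outcome per patient ending no earlier than the last visit, and the
    inclusion rule (at least one follow-up visit unless the patient died or
    was lost before the first annual visit).
    """
    v: list[Violation] = []
    b = cohort.baselines
    for _, row in b.iterrows():
        pid = row["patient_id"]
        if not (PSMS_MIN <= row["psms0"] <= PSMS_MAX):
            v.append(Violation(pid, "psms_range",
                               f"baseline PSMS {row['psms0']} outside [6, 30]"))
        if not (MMSE_MIN <= row["mmse0"] <= MMSE_MAX):
            v.append(Violation(pid, "mmse_range",
                               f"baseline MMSE {row['mmse0']} outside [0, 30]"))
        for colname in ("age_at_baseline", "education", "symptom_duration"):
            if row[colname] < 0:
                v.append(Violation(pid, "negative_value",
                                   f"{colname} = {row[colname]} < 0"))
    for pid, grp in cohort.visits.groupby("patient_id", sort=False):
        times = grp["visit_time"].to_numpy()
        if not np.all(np.diff(times) > 0):
            v.append(Violation(pid, "visit_order",
                               "visit times not strictly increasing"))
        bad = grp[(grp["psms"] < PSMS_MIN) | (grp["psms"] > PSMS_MAX)]
        for _, r in bad.iterrows():
            v.append(Violation(pid, "psms_range",
                               f"visit PSMS {r['psms']} at t={r['visit_time']} "
                               "outside [6, 30]"))
        mm = grp["mmse"].dropna()
        if ((mm < MMSE_MIN) | (mm > MMSE_MAX)).any():
            v.append(Violation(pid, "mmse_range", "visit MMSE outside [0, 30]"))
    outcomes = cohort.outcomes.set_index("patient_id")
    last_visit = cohort.visits.groupby("patient_id")["visit_time"].max()
    first_visit = cohort.visits.groupby("patient_id")["visit_time"].min()
    for pid in cohort.patient_ids:
        if pid not in outcomes.index:
            v.append(Violation(pid, "missing_outcome", "no outcome row"))
            continue
        out = outcomes.loc[pid]
        if out["followup_end"] < 0:
            v.append(Violation(pid, "negative_followup",
                               f"followup_end {out['followup_end']} < 0"))
        lv = last_visit.get(pid)
        if lv is not None and not np.isnan(lv) and out["followup_end"] < lv - 1e-9:
            v.append(Violation(pid, "followup_before_last_visit",
                               f"followup_end {out['followup_end']:.3f} before "
                               f"last visit {lv:.3f}"))
        if pid not in first_visit.index and out["status"] == "censored_admin":
            v.append(Violation(pid, "no_followup_visit",
                               "administratively censored with no follow-up visit"))
    return v
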