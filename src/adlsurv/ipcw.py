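"""Inverse-probability-of-censoring weights for loss to follow-up.

Loss to follow-up (patients who could not be re-contacted) is modelled with
a single logistic regression of the lost indicator on the nine baseline
covariates: age at first visit, sex, race, marital status, education,
baseline PSMS, baseline MMSE, symptom duration, and the cardiovascular
disease equivalent. Each patient then receives the fixed subject-level
weight 1 / (1 - p_lost(x)), attached to every one of their counting-process
rows, so that patients resembling those who were lost count for more.

This is deliberately the simple subject-level scheme (one weight per
patient from a single cross-sectional model), not the time-varying
product-form IPCW; see the methods note for the implications. Weights are
capped at a configurable quantile (default 99th) to guard against
near-separation of the dropout model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import Cohort

#: Baseline covariates of the loss-to-follow-up model.
DROPOUT_COVARIATES = [
    "age", "male", "nonwhite", "not_married", "education",
    "psms0", "mmse0", "symptom_duration", "cvde",
]


class DropoutModelError(RuntimeError):
    pass


class SeparationError(DropoutModelError):
    """A covariate (near-)perfectly predicts loss to follow-up."""


@dataclass
class DropoutModel:
    """Fitted logistic loss-to-follow-up model with per-patient risks."""

    covariates: list[str]
    coef: pd.Series               # includes "intercept"
    fitted: pd.Series             # P(lost | x), indexed by patient_id
    n_lost: int
    n: int

    def predict(self, X: pd.DataFrame) -> pd.Series:
        eta = self.coef["intercept"] + X[self.covariates] @ \
            self.coef[self.covariates]
        return 1.0 / (1.0 + np.exp(-eta))


def fit_dropout_model(cohort: Cohort,
                      covariates: list[str] | None = None) -> DropoutModel:
    """Maximum-likelihood logistic regression of the lost indicator.

    Passing ``covariates=[]`` fits the intercept-only model (fitted
    probability = observed lost fraction for everyone).
    """
    covariates = DROPOUT_COVARIATES if covariates is None else list(covariates)
    y = (cohort.outcomes.set_index("patient_id")["status"] == "lost")
    y = y.loc[cohort.patient_ids].astype(float)
    n_lost = int(y.sum())
    if n_lost == 0 or n_lost == len(y):
        raise DropoutModelError(
            f"degenerate outcome: {n_lost} of {len(y)} patients lost")
    if covariates:
        X = cohort.design_matrix(covariates)
        # constant columns carry no information and would break the MLE
        keep = [c for c in covariates if X[c].nunique() > 1]
        exog = np.hstack([np.ones((len(y), 1)), X[keep].to_numpy(float)])
    else:
        keep = []
        exog = np.ones((len(y), 1))
    names = ["intercept"] + keep

    def _name_worst(params):
        # covariate with the largest standardized effect is the offender
        if not keep:
            return "intercept"
        scale = exog[:, 1:].std(axis=0)
        return keep[int(np.argmax(np.abs(params[1:]) * scale))]

    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            res = sm.Logit(y.to_numpy(), exog).fit(disp=0, maxiter=200)
        params = np.asarray(res.params, float)
    except Exception as e:  # older statsmodels raises outright
        raise SeparationError(f"dropout model failed to fit: {e}") from e
    separated = any("erfect separation" in str(w.message) for w in caught)
    if separated or not res.mle_retvals.get("converged", True):
        raise SeparationError(
            f"covariate {_name_worst(params)!r} (quasi-)separates lost "
            "from retained patients")
    if not np.all(np.isfinite(params)):
        raise SeparationError("non-finite dropout-model coefficients")
    p = 1.0 / (1.0 + np.exp(-(exog @ params)))
    if np.any(p <= 0) or np.any(p >= 1):
        raise SeparationError("fitted loss probabilities reached 0 or 1")
    fitted = pd.Series(p, index=cohort.patient_ids, name="p_lost")
    return DropoutModel(keep, pd.Series(params, index=names),
                        fitted, n_lost, len(y))


def compute_weights(model: DropoutModel, cohort: Cohort,
                    cap_quantile: float = 0.99) -> pd.Series:
    """Subject-level IPCW: 1 / (1 - p_lost), capped at a weight quantile.

    The cap (default the 99th percentile of the raw weights) limits the
    influence of patients whose covariates make loss almost certain.
    Weights are always >= 1.
    """
    if sorted(model.fitted.index) != sorted(cohort.patient_ids):
        raise DropoutModelError("model was fitted on a different cohort")
    if not 0 < cap_quantile <= 1:
        raise ValueError("cap_quantile must be in (0, 1]")
    p = model.fitted.loc[cohort.patient_ids]
    if np.any(p >= 1):
        raise DropoutModelError("loss probability >= 1; weights undefined")
    w = 1.0 / (1.0 - p)
    cap = float(w.quantile(cap_quantile))
    return w.clip(upper=cap).rename("weight")
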