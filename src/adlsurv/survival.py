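"""From-scratch survival estimation machinery.

Implements the estimators the multistate analysis is built on:

* weighted Cox partial likelihood over ``(start, stop]`` counting-process
  rows (delayed entry = left truncation handled through the risk-set rule
  ``start < t <= stop``), maximised by Newton-Raphson with step-halving;
* Breslow cumulative baseline hazard;
* Schoenfeld-residual score test of proportional hazards against a
  time-varying coefficient ``beta(t) = beta + theta * g(t)`` with
  ``g`` = event-time rank;
* Kaplan-Meier product-limit curve and median;
* the two-sample log-rank test.

Ties are handled by the Breslow approximation by default (consistent with
the Breslow baseline); the Efron approximation is available by option.
Weights enter score, information and baseline hazard alike. Covariates are
centred at their weighted mean internally, so the baseline hazard refers to
an average-covariate subject; predictions re-apply the centring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


class EstimationError(RuntimeError):
    """The fit cannot proceed (no events, degenerate data...)."""


class SingularityError(EstimationError):
    """A covariate carries no information (constant within every risk set)."""


class MonotoneLikelihoodError(EstimationError):
    """The partial likelihood is maximised at infinite coefficients."""


# ---------------------------------------------------------------------------
# Step functions and survival curves


@dataclass(frozen=True)
class StepFunction:
    """Right-continuous non-decreasing step function with value 0 at t=0."""

    jump_times: np.ndarray
    increments: np.ndarray

    def __post_init__(self):
        jt = np.asarray(self.jump_times, dtype=float)
        inc = np.asarray(self.increments, dtype=float)
        if jt.shape != inc.shape or jt.ndim != 1:
            raise ValueError("jump_times and increments must be equal-length 1-d")
        if len(jt) and (np.any(np.diff(jt) <= 0) or jt[0] <= 0):
            raise ValueError("jump_times must be strictly increasing and > 0")
        if np.any(inc < 0):
            raise ValueError("increments must be non-negative")
        object.__setattr__(self, "jump_times", jt)
        object.__setattr__(self, "increments", inc)
        object.__setattr__(self, "_cum", np.cumsum(inc))

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.jump_times, t, side="right")
        cum = np.concatenate([[0.0], self._cum])
        out = cum[idx]
        return float(out) if out.ndim == 0 else out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.jump_times,
                             "increment": self.increments,
                             "cumulative": self._cum})


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit survival estimate: S(t), right-continuous, S(0)=1."""

    times: np.ndarray
    survival: np.ndarray

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right")
        s = np.concatenate([[1.0], self.survival])
        out = s[idx]
        return float(out) if out.ndim == 0 else out

    @property
    def median(self) -> float | None:
        """Smallest time with S(t) <= 0.5, or None if never reached."""
        below = np.nonzero(self.survival <= 0.5)[0]
        return float(self.times[below[0]]) if len(below) else None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "survival": self.survival})


# ---------------------------------------------------------------------------
# Cox model


@dataclass
class CoxFit:
    """A fitted (possibly weighted, possibly left-truncated) Cox model."""

    covariates: list[str]
    coef: pd.Series
    covariance: pd.DataFrame
    loglik: float
    loglik_trace: list[float]
    n_events: int
    n_rows: int
    converged: bool
    xbar: pd.Series            # centring point; baseline hazard refers to it
    baseline_cumhaz: StepFunction
    ties: str
    covariance_robust: pd.DataFrame | None = None

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.covariance)),
                         index=self.covariates)

    @property
    def se_robust(self) -> pd.Series:
        if self.covariance_robust is None:
            raise AttributeError("fit was made without robust=True")
        return pd.Series(np.sqrt(np.diag(self.covariance_robust)),
                         index=self.covariates)

    def summary(self, decimals: int | None = None,
                robust: bool = False) -> pd.DataFrame:
        """Hazard ratios with Wald 95% confidence intervals and p-values."""
        se = self.se_robust if robust else self.se
        z = self.coef / se
        out = pd.DataFrame({
            "coef": self.coef, "se": se,
            "hr": np.exp(self.coef),
            "hr_lo": np.exp(self.coef - 1.959963984540054 * se),
            "hr_hi": np.exp(self.coef + 1.959963984540054 * se),
            "z": z, "p": 2 * stats.norm.sf(np.abs(z)),
        })
        if decimals is not None:
            for c in ("hr", "hr_lo", "hr_hi"):
                out[c] = out[c].round(decimals)
        return out

    def linear_predictor(self, profile: pd.Series | dict) -> float:
        """beta . (z - xbar) for a covariate profile."""
        prof = pd.Series(profile)
        missing = [c for c in self.covariates if c not in prof.index]
        if missing:
            raise KeyError(f"profile is missing covariate(s): {missing}")
        z = prof[self.covariates].astype(float)
        return float(self.coef @ (z - self.xbar[self.covariates]))

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "covariates": self.covariates,
            "coef": self.coef.tolist(),
            "covariance": self.covariance.to_numpy().tolist(),
            "loglik": self.loglik,
            "loglik_trace": self.loglik_trace,
            "n_events": self.n_events,
            "n_rows": self.n_rows,
            "converged": self.converged,
            "xbar": self.xbar.tolist(),
            "ties": self.ties,
            "baseline_jump_times": self.baseline_cumhaz.jump_times.tolist(),
            "baseline_increments": self.baseline_cumhaz.increments.tolist(),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "CoxFit":
        s = str(text_or_path)
        text = s if s.lstrip().startswith("{") else Path(s).read_text()
        d = json.loads(text)
        cov = d["covariates"]
        return cls(
            covariates=cov,
            coef=pd.Series(d["coef"], index=cov),
            covariance=pd.DataFrame(d["covariance"], index=cov, columns=cov),
            loglik=d["loglik"], loglik_trace=d["loglik_trace"],
            n_events=d["n_events"], n_rows=d["n_rows"],
            converged=d["converged"],
            xbar=pd.Series(d["xbar"], index=cov), ties=d["ties"],
            baseline_cumhaz=StepFunction(np.array(d["baseline_jump_times"]),
                                         np.array(d["baseline_increments"])),
        )


def _extract_arrays(rows: pd.DataFrame, covariates: list[str]):
    start = rows["start"].to_numpy(float) if "start" in rows.columns \
        else np.zeros(len(rows))
    stop = rows["stop"].to_numpy(float)
    event = rows["event"].to_numpy(int)
    w = rows["weight"].to_numpy(float) if "weight" in rows.columns \
        else np.ones(len(rows))
    X = rows[covariates].to_numpy(float)
    if np.any(start >= stop):
        raise EstimationError("rows with start >= stop are not valid intervals")
    if np.any(w <= 0):
        raise EstimationError("weights must be positive")
    return start, stop, event, w, X


class _PartialLikelihood:
    """Breslow/Efron weighted partial likelihood with delayed entry.

    Risk-set sums S0/S1/S2 at each distinct event time are assembled from
    suffix cumulative sums over rows ordered by ``stop`` and by ``start``:
    the risk set at t is {i : start_i < t <= stop_i}, so a sum over it is
    (sum over stop_i >= t) - (sum over start_i >= t). Events at equal times
    are aggregated (events precede censorings by the (start, stop] rule).
    """

    def __init__(self, start, stop, event, w, X, ties="breslow"):
        if ties not in ("breslow", "efron"):
            raise ValueError(f"unknown tie rule {ties!r}")
        self.ties = ties
        self.n, self.p = X.shape
        ev = event.astype(bool)
        if not ev.any():
            raise EstimationError("no events in the data")
        self.w, self.X = w, X
        self.event_times, inv = np.unique(stop[ev], return_inverse=True)
        m = len(self.event_times)
        we = w[ev]
        Xe = X[ev]
        self.d = np.bincount(inv, weights=we, minlength=m)         # weighted
        self.d_count = np.bincount(inv, minlength=m)               # raw count
        self.sx = np.zeros((m, self.p))
        for k in range(self.p):
            self.sx[:, k] = np.bincount(inv, weights=we * Xe[:, k], minlength=m)
        # Efron needs within-tie exp-weighted sums; keep event row indices.
        self._ev_rows = np.nonzero(ev)[0]
        self._ev_group = inv
        # suffix-sum machinery
        self._stop_order = np.argsort(stop, kind="stable")
        self._start_order = np.argsort(start, kind="stable")
        self._stop_sorted = stop[self._stop_order]
        self._start_sorted = start[self._start_order]
        # searchsorted positions for each event time
        self._pos_stop = np.searchsorted(self._stop_sorted, self.event_times,
                                         side="left")
        self._pos_start = np.searchsorted(self._start_sorted, self.event_times,
                                          side="left")

    def _suffix(self, values: np.ndarray, order, pos) -> np.ndarray:
        """Suffix sums of `values` (n, ...) under `order`, read at `pos`."""
        v = values[order]
        suf = np.concatenate([np.cumsum(v[::-1], axis=0)[::-1],
                              np.zeros((1,) + v.shape[1:])])
        return suf[pos]

    def risk_sums(self, beta: np.ndarray):
        """S0 (m,), S1 (m,p), S2 (m,p,p) over risk sets at event times."""
        eta = self.X @ beta
        eta = np.clip(eta, -500, 500)
        r = self.w * np.exp(eta)
        rx = r[:, None] * self.X
        rxx = rx[:, :, None] * self.X[:, None, :]
        S0 = (self._suffix(r[:, None], self._stop_order, self._pos_stop)
              - self._suffix(r[:, None], self._start_order, self._pos_start))[:, 0]
        S1 = (self._suffix(rx, self._stop_order, self._pos_stop)
              - self._suffix(rx, self._start_order, self._pos_start))
        S2 = (self._suffix(rxx, self._stop_order, self._pos_stop)
              - self._suffix(rxx, self._start_order, self._pos_start))
        return r, S0, S1, S2

    def _efron_terms(self, beta, r, S0, S1, S2):
        """Per-event-time (loglik, U, I) contributions under Efron ties."""
        ll, U, I = 0.0, np.zeros(self.p), np.zeros((self.p, self.p))
        eta = np.clip(self.X @ beta, -500, 500)
        for j in range(len(self.event_times)):
            rows = self._ev_rows[self._ev_group == j]
            mj = len(rows)
            rD = r[rows]
            s0d = rD.sum()
            s1d = (rD[:, None] * self.X[rows]).sum(axis=0)
            s2d = (rD[:, None, None] * self.X[rows][:, :, None]
                   * self.X[rows][:, None, :]).sum(axis=0)
            wD = self.w[rows]
            ll += float(wD @ eta[rows])
            wbar = wD.mean()
            for l in range(mj):
                f = l / mj
                s0 = S0[j] - f * s0d
                s1 = S1[j] - f * s1d
                s2 = S2[j] - f * s2d
                m1 = s1 / s0
                ll -= wbar * np.log(s0)
                U += (self.sx[j] / mj) - wbar * m1
                I += wbar * (s2 / s0 - np.outer(m1, m1))
        return ll, U, I

    def evaluate(self, beta: np.ndarray):
        """(loglik, score, information) at beta."""
        r, S0, S1, S2 = self.risk_sums(beta)
        if np.any(S0 <= 0):
            raise EstimationError("empty risk set at an event time")
        if self.ties == "efron":
            return self._efron_terms(beta, r, S0, S1, S2)
        m1 = S1 / S0[:, None]
        ll = float((self.sx * beta).sum() - (self.d * np.log(S0)).sum())
        U = (self.sx - self.d[:, None] * m1).sum(axis=0)
        V = S2 / S0[:, None, None] - m1[:, :, None] * m1[:, None, :]
        I = (self.d[:, None, None] * V).sum(axis=0)
        return ll, U, I

    def loglik(self, beta: np.ndarray) -> float:
        return self.evaluate(np.asarray(beta, float))[0]


def _score_residuals(pl: _PartialLikelihood, beta, start, stop, w, Xc):
    """Per-row score residuals (Lin-Wei); they sum to ~0 at the MLE."""
    r, S0, S1, _ = pl.risk_sums(beta)
    m1 = S1 / S0[:, None]
    inc = pl.d / S0
    cumA = np.concatenate([[0.0], np.cumsum(inc)])
    cumB = np.vstack([np.zeros(pl.p), np.cumsum(inc[:, None] * m1, axis=0)])
    lo = np.searchsorted(pl.event_times, start, side="right")
    hi = np.searchsorted(pl.event_times, stop, side="right")
    A = cumA[hi] - cumA[lo]
    B = cumB[hi] - cumB[lo]
    U = -(r[:, None] * (Xc * A[:, None] - B))
    U[pl._ev_rows] += w[pl._ev_rows, None] * (Xc[pl._ev_rows]
                                              - m1[pl._ev_group])
    return U


def fit_cox(rows: pd.DataFrame, covariates: list[str], *,
            ties: str = "breslow", tol: float = 1e-9, max_iter: int = 50,
            max_halvings: int = 10, robust: bool = False) -> CoxFit:
    """Fit a weighted Cox model on counting-process rows.

    ``rows`` needs ``stop`` and ``event`` columns; ``start`` defaults to 0
    (no delayed entry) and ``weight`` to 1. Covariates are centred at their
    weighted mean before optimisation; coefficients are unaffected and the
    Breslow baseline then refers to the centring point (stored as ``xbar``).

    ``robust=True`` additionally computes the Lin-Wei sandwich covariance
    from per-subject score residuals, clustered on ``patient_id`` when the
    column is present — the appropriate variance when rows carry sampling
    or censoring weights (the model-based variance is anti-conservative
    then). Available for Breslow ties only.

    Raises
    ------
    EstimationError  if there are no events,
    SingularityError if a covariate is constant within every risk set,
    MonotoneLikelihoodError if the Newton path diverges (|beta| > 50).
    """
    covariates = list(covariates)
    start, stop, event, w, X = _extract_arrays(rows, covariates)
    xbar = (w[:, None] * X).sum(axis=0) / w.sum()
    Xc = X - xbar
    pl = _PartialLikelihood(start, stop, event, w, Xc, ties=ties)

    beta = np.zeros(len(covariates))
    ll, U, I = pl.evaluate(beta)
    diag = np.diag(I)
    if np.any(diag <= 1e-12):
        bad = covariates[int(np.argmin(diag))]
        raise SingularityError(
            f"covariate {bad!r} carries no information (constant within "
            "every risk set)")
    trace = [ll]
    converged = False
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(I, U)
        except np.linalg.LinAlgError as e:
            raise SingularityError(f"singular information matrix: {e}") from e
        new_beta = beta + step
        if np.any(np.abs(new_beta) > 50):
            raise MonotoneLikelihoodError(
                "coefficients diverging (|beta| > 50); the partial "
                "likelihood appears monotone")
        new_ll, new_U, new_I = pl.evaluate(new_beta)
        halv = 0
        while new_ll < ll - 1e-12 and halv < max_halvings:
            step = step / 2.0
            new_beta = beta + step
            new_ll, new_U, new_I = pl.evaluate(new_beta)
            halv += 1
        delta = new_ll - ll
        beta, ll, U, I = new_beta, new_ll, new_U, new_I
        trace.append(ll)
        if abs(delta) < tol:
            converged = True
            break

    cov = np.linalg.inv(I)
    cov = (cov + cov.T) / 2.0
    cov_robust = None
    if robust:
        if ties != "breslow":
            raise EstimationError("robust variance implemented for Breslow "
                                  "ties only")
        U = _score_residuals(pl, beta, start, stop, w, Xc)
        if "patient_id" in rows.columns:
            Udf = pd.DataFrame(U).groupby(
                rows["patient_id"].to_numpy()).sum().to_numpy()
        else:
            Udf = U
        G = Udf.T @ Udf
        cr = cov @ G @ cov
        cov_robust = pd.DataFrame((cr + cr.T) / 2.0, index=covariates,
                                  columns=covariates)
    baseline = _breslow_from_pl(pl, beta)
    return CoxFit(
        covariates=covariates,
        coef=pd.Series(beta, index=covariates),
        covariance=pd.DataFrame(cov, index=covariates, columns=covariates),
        loglik=ll, loglik_trace=trace,
        n_events=int(event.sum()), n_rows=len(rows), converged=converged,
        xbar=pd.Series(xbar, index=covariates),
        baseline_cumhaz=baseline, ties=ties, covariance_robust=cov_robust,
    )


def _breslow_from_pl(pl: _PartialLikelihood, beta: np.ndarray) -> StepFunction:
    _, S0, _, _ = pl.risk_sums(beta)
    return StepFunction(pl.event_times, pl.d / S0)


def breslow_baseline(fit: CoxFit, rows: pd.DataFrame) -> StepFunction:
    """Breslow cumulative baseline hazard of `fit` evaluated on `rows`.

    Increment at each distinct event time = weighted event mass divided by
    the risk-set sum of weight * exp(beta . (x - xbar)). Invariant under a
    common rescaling of the weights.
    """
    if not fit.converged:
        raise EstimationError("breslow_baseline requires a converged fit")
    start, stop, event, w, X = _extract_arrays(rows, fit.covariates)
    Xc = X - fit.xbar.to_numpy()
    pl = _PartialLikelihood(start, stop, event, w, Xc, ties=fit.ties)
    return _breslow_from_pl(pl, fit.coef.to_numpy())


def nelson_aalen(rows: pd.DataFrame) -> StepFunction:
    """Nelson-Aalen cumulative hazard on counting-process rows.

    Increment at each event time = weighted events / weighted number at
    risk; identical to the Breslow baseline of a model with all
    coefficients zero.
    """
    start, stop, event, w, _ = _extract_arrays(rows.assign(_z=0.0), ["_z"])
    pl = _PartialLikelihood(start, stop, event, w, np.zeros((len(stop), 0)))
    return _breslow_from_pl(pl, np.zeros(0))


# ---------------------------------------------------------------------------
# Schoenfeld proportional-hazards diagnostic


@dataclass(frozen=True)
class PHTestResult:
    """Score test of PH against beta(t) = beta + theta * rank(t)."""

    covariates: list[str]
    correlation: pd.Series   # Pearson corr(residual, event-time rank)
    chi2: pd.Series
    p: pd.Series
    global_chi2: float
    global_p: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"correlation": self.correlation,
                             "chi2": self.chi2, "p": self.p})


def schoenfeld_residuals(fit: CoxFit, rows: pd.DataFrame) -> pd.DataFrame:
    """Per-event Schoenfeld residuals x_i - xbar(t_i) at the fitted beta."""
    start, stop, event, w, X = _extract_arrays(rows, fit.covariates)
    Xc = X - fit.xbar.to_numpy()
    pl = _PartialLikelihood(start, stop, event, w, Xc, ties=fit.ties)
    _, S0, S1, _ = pl.risk_sums(fit.coef.to_numpy())
    m1 = S1 / S0[:, None]
    res = Xc[pl._ev_rows] - m1[pl._ev_group]
    out = pd.DataFrame(res, columns=fit.covariates)
    out.insert(0, "time", stop[pl._ev_rows])
    out.insert(1, "weight", w[pl._ev_rows])
    out.insert(2, "rank", pl._ev_group.astype(float))
    return out.sort_values("time", kind="stable").reset_index(drop=True)


def schoenfeld_ph_test(fit: CoxFit, rows: pd.DataFrame) -> PHTestResult:
    """Proportional-hazards diagnostic from Schoenfeld residuals.

    The statistic is the score test for a time-interaction coefficient with
    g(t) = rank of the distinct event time, using the information of the
    interaction after profiling out the main effects; per-covariate 1-df
    chi-square plus a global p-df test, alongside the plain Pearson
    correlation of residual with event rank.
    """
    start, stop, event, w, X = _extract_arrays(rows, fit.covariates)
    if int(event.sum()) < 3:
        raise EstimationError("Schoenfeld test needs at least 3 events")
    Xc = X - fit.xbar.to_numpy()
    pl = _PartialLikelihood(start, stop, event, w, Xc, ties=fit.ties)
    _, S0, S1, S2 = pl.risk_sums(fit.coef.to_numpy())
    m1 = S1 / S0[:, None]
    V = S2 / S0[:, None, None] - m1[:, :, None] * m1[:, None, :]
    g = np.arange(len(pl.event_times), dtype=float)
    gbar = float((pl.d * g).sum() / pl.d.sum())
    gc = g - gbar
    # score for the interaction at theta=0 (main-effect score is 0 at betahat)
    u = (gc[:, None] * (pl.sx - pl.d[:, None] * m1)).sum(axis=0)
    dV = pl.d[:, None, None] * V
    I_bb = dV.sum(axis=0)
    I_tb = (g[:, None, None] * dV).sum(axis=0)
    I_tt = ((g ** 2)[:, None, None] * dV).sum(axis=0)
    A = I_tt - I_tb @ np.linalg.solve(I_bb, I_tb)
    A = (A + A.T) / 2.0
    diagA = np.clip(np.diag(A), 1e-300, None)
    chi2 = u ** 2 / diagA
    p = stats.chi2.sf(chi2, df=1)
    gchi2 = float(u @ np.linalg.solve(A, u))
    gp = float(stats.chi2.sf(gchi2, df=len(fit.covariates)))
    res = schoenfeld_residuals(fit, rows)
    corr = np.array([
        np.corrcoef(res[c], res["rank"])[0, 1] if res[c].std() > 0 else 0.0
        for c in fit.covariates])
    idx = fit.covariates
    return PHTestResult(idx, pd.Series(corr, index=idx),
                        pd.Series(chi2, index=idx), pd.Series(p, index=idx),
                        gchi2, gp)


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank


def km_curve(times, events, weights=None) -> SurvivalCurve:
    """Weighted Kaplan-Meier product-limit estimator.

    Right-censored data on a single time scale (no delayed entry); at tied
    times events are processed before censorings.
    """
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    w = np.ones_like(t) if weights is None else np.asarray(weights, float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    ut = np.unique(t[e == 1])
    surv = []
    s = 1.0
    for tj in ut:
        n_risk = w[t >= tj].sum()
        d = w[(t == tj) & (e == 1)].sum()
        s *= max(0.0, 1.0 - d / n_risk)
        surv.append(s)
    return SurvivalCurve(ut, np.asarray(surv))


def km_median(curve: SurvivalCurve) -> float | None:
    return curve.median


def logrank_test(group1, group2):
    """Two-sample log-rank test, 1 df.

    Each group is (times, events). Returns ``{"chi2": ..., "p": ...}``.
    """
    t1, e1 = (np.asarray(a) for a in group1)
    t2, e2 = (np.asarray(a) for a in group2)
    if len(t1) == 0 or len(t2) == 0:
        raise ValueError("both groups must be non-empty")
    times = np.concatenate([t1, t2])
    events = np.concatenate([e1, e2]).astype(int)
    grp = np.concatenate([np.zeros(len(t1), int), np.ones(len(t2), int)])
    ut = np.unique(times[events == 1])
    O1 = E1 = V = 0.0
    for tj in ut:
        at_risk = times >= tj
        n = at_risk.sum()
        n1 = (at_risk & (grp == 0)).sum()
        dead = (times == tj) & (events == 1)
        d = dead.sum()
        d1 = (dead & (grp == 0)).sum()
        O1 += d1
        E1 += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if V == 0:
        return {"chi2": 0.0, "p": 1.0}
    chi2 = (O1 - E1) ** 2 / V
    return {"chi2": float(chi2), "p": float(stats.chi2.sf(chi2, df=1))}
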