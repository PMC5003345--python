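import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize, minimize_scalar

from adlsurv.survival import (EstimationError, MonotoneLikelihoodError,
                              SingularityError, StepFunction, breslow_baseline,
                              fit_cox, km_curve, km_median, logrank_test,
                              nelson_aalen, schoenfeld_ph_test,
                              schoenfeld_residuals, CoxFit)


def naive_partial_loglik(beta, start, stop, event, X, w):
    """Independent O(n^2) Breslow partial log-likelihood (loop-based)."""
    beta = np.atleast_1d(beta)
    ll = 0.0
    for j in np.flatnonzero(event):
        tj = stop[j]
        risk = (start < tj) & (tj <= stop)
        ll += w[j] * (X[j] @ beta) \
            - w[j] * np.log(np.sum(w[risk] * np.exp(X[risk] @ beta)))
    return ll


def brute_force_beta(rows, covariates):
    start = rows.get("start", pd.Series(0.0, index=rows.index)).to_numpy(float)
    stop = rows["stop"].to_numpy(float)
    event = rows["event"].to_numpy(int)
    w = rows.get("weight", pd.Series(1.0, index=rows.index)).to_numpy(float)
    X = rows[covariates].to_numpy(float)
    if len(covariates) == 1:
        res = minimize_scalar(
            lambda b: -naive_partial_loglik(b, start, stop, event, X, w),
            bounds=(-5, 5), method="bounded", options={"xatol": 1e-10})
        return np.array([res.x]), -res.fun
    res = minimize(
        lambda b: -naive_partial_loglik(b, start, stop, event, X, w),
        np.zeros(len(covariates)), method="Nelder-Mead",
        options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 20000})
    return res.x, -res.fun


TOY = pd.DataFrame({"stop": [1, 2, 3, 4, 5, 6.0],
                    "event": [1, 1, 0, 1, 0, 1],
                    "x": [1, 0, 1, 0, 1, 0.0]})

WEIGHTED5 = pd.DataFrame({
    "start": [0, 0, 1, 0, 2.0], "stop": [2, 3, 4, 5, 6.0],
    "event": [1, 0, 1, 1, 0], "x": [1, 0, 0, 1, 1.0],
    "weight": [2.0, 1.0, 1.5, 1.0, 0.5]})


class TestCoxOracle:
    def test_six_subject_toy_matches_brute_force(self):
        fit = fit_cox(TOY, ["x"])
        b_star, ll_star = brute_force_beta(TOY, ["x"])
        assert fit.coef["x"] == pytest.approx(b_star[0], abs=1e-4)
        assert fit.loglik == pytest.approx(ll_star, abs=1e-6)
        # frozen values from the grid/golden-section maximizer
        assert fit.coef["x"] == pytest.approx(-0.34014377, abs=1e-4)
        assert fit.loglik == pytest.approx(-4.46068250, abs=1e-4)

    def test_weighted_delayed_entry_fixture_matches_brute_force(self):
        fit = fit_cox(WEIGHTED5, ["x"])
        b_star, _ = brute_force_beta(WEIGHTED5, ["x"])
        assert fit.coef["x"] == pytest.approx(b_star[0], abs=1e-4)
        assert fit.coef["x"] == pytest.approx(0.18406353, abs=1e-4)

    def test_two_covariates_match_brute_force(self):
        rng = np.random.default_rng(7)
        n = 9
        rows = pd.DataFrame({
            "stop": rng.uniform(1, 10, n).round(2),
            "event": [1, 1, 1, 0, 1, 0, 1, 1, 0],
            "x1": rng.binomial(1, 0.5, n).astype(float),
            "x2": rng.normal(0, 1, n).round(2)})
        fit = fit_cox(rows, ["x1", "x2"])
        b_star, ll_star = brute_force_beta(rows, ["x1", "x2"])
        assert np.allclose(fit.coef.to_numpy(), b_star, atol=1e-4)
        assert fit.loglik == pytest.approx(ll_star, abs=1e-6)

    def test_oracle_se_from_numeric_hessian(self):
        """Wald SEs agree with the curvature of the independent loglik."""
        fit = fit_cox(TOY, ["x"])
        b = fit.coef["x"]
        h = 1e-4
        args = (np.zeros(len(TOY)), TOY["stop"].to_numpy(float),
                TOY["event"].to_numpy(int),
                TOY[["x"]].to_numpy(float), np.ones(len(TOY)))
        d2 = (naive_partial_loglik(b + h, *args)
              - 2 * naive_partial_loglik(b, *args)
              + naive_partial_loglik(b - h, *args)) / h ** 2
        assert fit.se["x"] == pytest.approx(np.sqrt(-1 / d2), rel=1e-4)


class TestCoxErrors:
    def test_no_events_is_estimation_error(self):
        rows = TOY.assign(event=0)
        with pytest.raises(EstimationError):
            fit_cox(rows, ["x"])

    def test_constant_covariate_is_singular_and_named(self):
        rows = TOY.assign(x=1.0)
        with pytest.raises(SingularityError, match="'x'"):
            fit_cox(rows, ["x"])

    def test_perfectly_separating_covariate_diverges(self):
        # covariate exactly orders the event times: monotone likelihood
        rows = pd.DataFrame({"stop": np.arange(1.0, 9.0),
                             "event": np.ones(8, int),
                             "x": np.arange(8.0) / 10.0})
        with pytest.raises(MonotoneLikelihoodError):
            fit_cox(rows, ["x"])


class TestDelayedEntry:
    def test_truncation_at_zero_changes_nothing(self):
        fit0 = fit_cox(TOY, ["x"])
        fit1 = fit_cox(TOY.assign(start=0.0), ["x"])
        assert fit0.coef["x"] == pytest.approx(fit1.coef["x"], abs=1e-12)

    def test_truncation_removes_early_risk_contribution(self):
        """Entering after the first event time drops that subject from the
        first risk set; the fixture's brute force confirms the new MLE."""
        rows = TOY.assign(start=[0, 0, 1.5, 0, 0, 0.0])
        fit = fit_cox(rows, ["x"])
        b_star, _ = brute_force_beta(rows, ["x"])
        assert fit.coef["x"] == pytest.approx(b_star[0], abs=1e-4)
        assert fit.coef["x"] != pytest.approx(
            fit_cox(TOY, ["x"]).coef["x"], abs=1e-6)


class TestBreslowBaseline:
    def test_beta_zero_equals_nelson_aalen(self):
        rows = pd.DataFrame({"start": [0, 0, 0.0], "stop": [1, 2, 3.0],
                             "event": [1, 1, 0]})
        na = nelson_aalen(rows)
        assert np.allclose(na.jump_times, [1.0, 2.0])
        assert np.allclose(na.increments, [1 / 3, 1 / 2])

    def test_weight_rescaling_invariance(self):
        fit = fit_cox(WEIGHTED5, ["x"])
        sf1 = breslow_baseline(fit, WEIGHTED5)
        doubled = WEIGHTED5.assign(weight=WEIGHTED5["weight"] * 2)
        fit2 = fit_cox(doubled, ["x"])
        sf2 = breslow_baseline(fit2, doubled)
        assert np.allclose(sf1.increments, sf2.increments)

    def test_weighted_fixture_matches_direct_formula(self):
        """Increment = weighted event mass / risk-set sum of w * exp(eta),
        evaluated by hand at the (brute-force) MLE on the 5-row fixture."""
        fit = fit_cox(WEIGHTED5, ["x"])
        sf = breslow_baseline(fit, WEIGHTED5)
        b = fit.coef["x"]
        xc = WEIGHTED5["x"] - fit.xbar["x"]
        expected = []
        for tj, wj in [(2.0, 2.0), (4.0, 1.5), (5.0, 1.0)]:
            risk = (WEIGHTED5["start"] < tj) & (tj <= WEIGHTED5["stop"])
            s0 = np.sum(WEIGHTED5["weight"][risk] * np.exp(b * xc[risk]))
            expected.append(wj / s0)
        assert np.allclose(sf.jump_times, [2.0, 4.0, 5.0])
        assert np.allclose(sf.increments, expected)
        # frozen hand computation at the uncentred MLE; the centred
        # baseline differs by the factor exp(beta * xbar)
        frozen_uncentred = np.array([0.32753184, 0.45411359, 0.55458864])
        assert np.allclose(sf.increments,
                           frozen_uncentred * np.exp(b * fit.xbar["x"]),
                           rtol=1e-4)

    def test_step_function_evaluation_right_continuous(self):
        sf = StepFunction(np.array([1.0, 2.0]), np.array([0.05, 0.07]))
        assert sf(0.0) == 0.0
        assert sf(1.0) == pytest.approx(0.05)
        assert sf(1.5) == pytest.approx(0.05)
        assert sf(2.0) == pytest.approx(0.12)
        assert np.allclose(sf([0.5, 1.0, 3.0]), [0.0, 0.05, 0.12])


class TestKaplanMeier:
    def test_single_subject_event(self):
        c = km_curve([5.0], [1])
        assert km_median(c) == 5.0

    def test_hand_product_limit(self):
        c = km_curve([1, 2, 3, 4.0], [1, 1, 1, 1])
        assert np.allclose(c.survival, [0.75, 0.5, 0.25, 0.0])
        assert c(2.0) == pytest.approx(0.5)
        assert km_median(c) == 2.0

    def test_median_none_when_curve_stays_high(self):
        c = km_curve([1, 2, 3, 4.0], [1, 0, 0, 0])
        assert km_median(c) is None

    def test_censoring_after_tied_event_keeps_risk_set(self):
        # at t=2: 3 at risk (event processed before the censoring at 2)
        c = km_curve([1, 2, 2, 4.0], [1, 1, 0, 0])
        assert np.allclose(c.survival, [0.75, 0.75 * (1 - 1 / 3)])


class TestLogrank:
    def test_identical_groups_give_zero(self):
        g = ([1, 2, 3, 4.0], [1, 1, 0, 1])
        out = logrank_test(g, g)
        assert out["chi2"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_tabulated_example(self):
        """4 vs 4 subjects, no ties: chi2 from direct O-E risk-set table."""
        t1, e1 = np.array([1, 3, 5, 7.0]), np.array([1, 1, 0, 1])
        t2, e2 = np.array([2, 4, 6, 8.0]), np.array([1, 0, 1, 1])
        out = logrank_test((t1, e1), (t2, e2))
        times = np.concatenate([t1, t2])
        events = np.concatenate([e1, e2])
        grp = np.array([0] * 4 + [1] * 4)
        O1 = E1 = V = 0.0
        for tj in sorted(times[events == 1]):
            at = times >= tj
            n, n1 = at.sum(), (at & (grp == 0)).sum()
            d1 = ((times == tj) & (events == 1) & (grp == 0)).sum()
            O1 += d1
            E1 += n1 / n
            if n > 1:   # single death, so the hypergeometric factor is 1
                V += (n1 / n) * (1 - n1 / n)
        assert out["chi2"] == pytest.approx((O1 - E1) ** 2 / V)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test(([], []), ([1.0], [1]))


class TestSchoenfeld:
    def test_residuals_sum_to_zero_at_mle(self):
        rng = np.random.default_rng(11)
        n = 80
        x = rng.normal(0, 1, n)
        t = rng.exponential(1 / (0.2 * np.exp(0.4 * x)))
        c = rng.uniform(1, 10, n)
        rows = pd.DataFrame({"start": 0.0, "stop": np.minimum(t, c),
                             "event": (t <= c).astype(int), "x": x})
        fit = fit_cox(rows, ["x"])
        res = schoenfeld_residuals(fit, rows)
        weighted_sum = (res["weight"] * res["x"]).sum()
        assert weighted_sum == pytest.approx(0.0, abs=1e-6)

    def test_too_few_events_rejected(self):
        rows = pd.DataFrame({"start": [0, 0, 0.0], "stop": [1, 2, 3.0],
                             "event": [1, 1, 0], "x": [1, 0, 1.0]})
        fit = fit_cox(rows, ["x"], max_iter=5)
        with pytest.raises(EstimationError, match="3 events"):
            schoenfeld_ph_test(fit, rows)

    def test_detects_strongly_time_varying_effect(self):
        """A coefficient that jumps mid-follow-up must be flagged while a
        well-specified covariate is not."""
        rng = np.random.default_rng(13)
        n = 500
        x = rng.binomial(1, 0.5, n)
        z = rng.normal(0, 1, n)
        t0 = rng.exponential(1 / (0.15 * np.exp(-0.3 * z)))
        t = np.where(t0 < 2, t0,
                     2 + rng.exponential(1 / (0.15 * np.exp(1.2 * x
                                                            - 0.3 * z))))
        c = rng.uniform(2, 12, n)
        rows = pd.DataFrame({"start": 0.0, "stop": np.minimum(t, c),
                             "event": (t <= c).astype(int), "x": x, "z": z})
        fit = fit_cox(rows, ["x", "z"])
        res = schoenfeld_ph_test(fit, rows)
        assert res.p["x"] < 0.05
        assert res.global_p < 0.05
        assert res.p["z"] > 0.05


class TestSerialization:
    def test_json_round_trip(self):
        fit = fit_cox(WEIGHTED5, ["x"])
        again = CoxFit.from_json(fit.to_json())
        assert again.coef["x"] == fit.coef["x"]
        assert np.allclose(again.covariance.to_numpy(),
                           fit.covariance.to_numpy())
        assert np.allclose(again.baseline_cumhaz.increments,
                           fit.baseline_cumhaz.increments)

    def test_efron_option_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(5)
        n = 120
        x = rng.normal(0, 1, n)
        t = np.round(rng.exponential(1 / (0.3 * np.exp(0.5 * x))), 1) + 0.1
        rows = pd.DataFrame({"start": 0.0, "stop": t, "event": 1, "x": x})
        fit = fit_cox(rows, ["x"], ties="efron")
        cph = lifelines.CoxPHFitter().fit(
            pd.DataFrame({"T": t, "E": 1, "x": x}), "T", "E")
        assert fit.coef["x"] == pytest.approx(cph.params_["x"], abs=1e-5)
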