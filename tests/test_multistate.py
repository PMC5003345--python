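import numpy as np
import pandas as pd
import pytest

import adlsurv as a
from adlsurv.multistate import (EmptyTransitionError, average_profile,
                                conditional_death_probability, figure2_curves,
                                fit_multistate)
from adlsurv.survival import StepFunction, fit_cox
from adlsurv.impairment import counting_process
from conftest import build_cohort


def _make_ms_with_baseline(jumps, incs, coef=None):
    """Hand-built post-impairment fit for closed-form probability checks."""
    covs = ["male"]
    coef = coef if coef is not None else {"male": 0.0}
    fit = a.CoxFit(
        covariates=covs, coef=pd.Series(coef),
        covariance=pd.DataFrame(np.eye(1), index=covs, columns=covs),
        loglik=0.0, loglik_trace=[0.0], n_events=1, n_rows=1, converged=True,
        xbar=pd.Series({"male": 0.0}),
        baseline_cumhaz=StepFunction(np.asarray(jumps, float),
                                     np.asarray(incs, float)),
        ties="breslow")
    return a.MultistateFit(fit, fit, fit, a.DEF1, covs, 1, 1, 0, False)


class TestConditionalProbability:
    def test_linear_cumhaz_closed_form(self):
        # H0(t) = 0.1 t via fine steps; lp = 0 at t = 6 -> 1 - e^-0.6
        grid = np.arange(0.01, 6.01, 0.01)
        ms = _make_ms_with_baseline(grid, np.full(len(grid), 0.001))
        cur = conditional_death_probability(ms, {"male": 0.0}, "impaired",
                                            [6.0])
        assert cur["prob_death"].iloc[0] == pytest.approx(1 - np.exp(-0.6),
                                                          abs=1e-4)

    def test_linear_predictor_ln2_doubles_hazard(self):
        grid = np.arange(0.01, 6.01, 0.01)
        ms = _make_ms_with_baseline(grid, np.full(len(grid), 0.001),
                                    coef={"male": np.log(2)})
        cur = conditional_death_probability(ms, {"male": 1.0}, "impaired",
                                            [6.0])
        assert cur["prob_death"].iloc[0] == pytest.approx(1 - np.exp(-1.2),
                                                          abs=1e-4)

    def test_step_baseline_between_jumps(self):
        ms = _make_ms_with_baseline([1.0, 2.0], [0.05, 0.07])
        cur = conditional_death_probability(ms, {"male": 0.0}, "impaired",
                                            [0.0, 1.5, 2.5])
        assert cur["prob_death"].tolist() == pytest.approx(
            [0.0, 1 - np.exp(-0.05), 1 - np.exp(-0.12)])

    def test_missing_profile_covariate_is_named(self):
        ms = _make_ms_with_baseline([1.0], [0.1])
        with pytest.raises(KeyError, match="male"):
            conditional_death_probability(ms, {"age": 70.0}, "intact", [1.0])

    def test_unknown_state_rejected(self):
        ms = _make_ms_with_baseline([1.0], [0.1])
        with pytest.raises(ValueError, match="state"):
            conditional_death_probability(ms, {"male": 0.0}, "zombie", [1.0])


class TestFitMultistate:
    def test_risk_set_conservation_both_definitions(self):
        cohort, _ = a.simulate_cohort(a.study_like_scenario(n=500, seed=21))
        deaths = int((cohort.outcomes["status"] == "dead").sum())
        for d in ("def1_psms_ge7", "def2_delta_ge2"):
            ms = fit_multistate(cohort, d)
            acct = ms.event_accounting()
            assert acct["death_pre_impairment"] \
                + acct["death_post_impairment"] == deaths
            assert acct["impairment"] == ms.n_onsets

    def test_no_onsets_gives_named_error_and_d1_equals_plain_fit(self):
        scen = a.dropout_bias_scenario(n=300, seed=5)   # impairment off
        cohort, _ = a.simulate_cohort(scen)
        with pytest.raises(EmptyTransitionError, match="impairment"):
            fit_multistate(cohort, "def1_psms_ge7")
        ms = fit_multistate(cohort, "def1_psms_ge7", allow_partial=True,
                            covariates=["male", "age"])
        assert ms.fit_I is None and "impairment" in ms.gaps
        rows = counting_process(cohort, "def1_psms_ge7", ["male", "age"])
        plain = fit_cox(rows, ["male", "age"])
        assert np.allclose(ms.fit_D1.coef, plain.coef, atol=1e-10)

    def test_transition_effect_recovery_on_known_truth(self):
        """With a known sex effect on post-impairment death, the D2 fit
        lands within 3 SE of truth at n = 2000."""
        cohort, truth = a.simulate_cohort(a.study_like_scenario(n=2000,
                                                               seed=77))
        ms = fit_multistate(cohort, "def1_psms_ge7")
        for key, fit in (("I", ms.fit_I), ("D1", ms.fit_D1),
                         ("D2", ms.fit_D2)):
            beta = truth.true_beta(key)
            assert abs(fit.coef["male"] - beta["male"]) \
                < 3 * fit.se["male"]

    def test_zero_effects_make_curves_profile_invariant(self):
        scen = a.constant_intensity_scenario(n=2500, seed=3)
        cohort, _ = a.simulate_cohort(scen)
        ms = fit_multistate(cohort, "def1_psms_ge7")
        grid = [1.0, 3.0, 5.0]
        p1 = conditional_death_probability(
            ms, average_profile(), "intact", grid)["prob_death"]
        prof2 = average_profile(age=68.0, male=1.0, education=10.0,
                                mmse0=12.0)
        p2 = conditional_death_probability(
            ms, prof2, "intact", grid)["prob_death"]
        # effects are all zero in truth; fitted effects differ only by noise
        assert np.allclose(p1, p2, atol=0.1)


class TestFigure2Curves:
    @pytest.fixture(scope="class")
    def curves(self):
        cohort, _ = a.simulate_cohort(a.study_like_scenario(n=4000, seed=42))
        ms = {d: fit_multistate(cohort, d)
              for d in ("def1_psms_ge7", "def2_delta_ge2")}
        return figure2_curves(ms, average_profile(), horizon=6.0)

    def test_four_curves_per_definition(self, curves):
        combos = curves.groupby(["definition", "sex", "state"]).size()
        assert len(combos) == 8

    def test_probability_bounds_and_monotonicity(self, curves):
        assert curves["prob_death"].between(0, 1).all()
        for _, grp in curves.groupby(["definition", "sex", "state"]):
            assert (np.diff(grp["prob_death"]) >= -1e-12).all()

    def test_zero_at_time_zero(self, curves):
        assert (curves.loc[curves["time"] == 0, "prob_death"] == 0).all()

    def test_impaired_dominates_intact_absolute_definition(self, curves):
        """Post-impairment mortality dominates in the study-like scenario,
        so the impaired curve sits above the intact curve for each sex.
        Under the absolute rule the baseline-impaired give the impaired
        state support from t = 0, so the whole horizon is comparable."""
        wide = curves.pivot_table(index=["definition", "sex", "time"],
                                  columns="state", values="prob_death")
        d1 = wide.loc["def1_psms_ge7"]
        late = d1[d1.index.get_level_values("time") >= 0.5]
        assert (late["impaired"] >= late["intact"] - 1e-9).all()

    def test_impaired_dominates_intact_relative_definition(self):
        """The relative rule is checked on an all-intact-at-entry cohort
        (flat-trajectory impaired entrants would otherwise dilute the
        'intact' state); before ~2y the left-truncated impaired baseline
        has no support, so dominance is asserted beyond it."""
        s = a.study_like_scenario(n=3000, seed=43)
        s.p_baseline_intact = 1.0
        cohort, _ = a.simulate_cohort(s)
        ms = fit_multistate(cohort, "def2_delta_ge2")
        curves = figure2_curves({"def2_delta_ge2": ms}, average_profile(),
                                horizon=6.0)
        wide = curves.pivot_table(index=["sex", "time"], columns="state",
                                  values="prob_death")
        late = wide[wide.index.get_level_values("time") >= 2.0]
        assert (late["impaired"] >= late["intact"] - 1e-9).all()
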