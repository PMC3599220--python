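"""Weibull PH likelihood, fitting, and absolute-risk prediction."""

import math

import numpy as np
import pandas as pd
import pytest
from lifelines import WeibullFitter

import cvdscore as cs
from cvdscore.published import GLUCOSE_MODEL
from cvdscore.weibull import MODEL_COVARIATES

from conftest import make_table


class TestLinearPredictor:
    def test_all_zero_covariates_give_zero(self):
        prof = {"sex": "male", "age": 50, "smoking": 0.0, "sbp": 0.0, "glucose": 0.0}
        m = cs.WeibullPHModel(alpha={"male": -40}, shape={"male": 9},
                              beta={"smoking": 0.4, "sbp": 0.01, "glucose": 0.1})
        assert cs.linear_predictor(m, prof) == 0.0

    def test_published_worked_profile(self):
        """Smoker, SBP 180, glucose 6: 0.37 + 0.01*180 + 0.10*6 = 2.77."""
        prof = {"sex": "male", "age": 65, "smoking": 1.0, "sbp": 180, "glucose": 6}
        assert cs.linear_predictor(GLUCOSE_MODEL, prof) == pytest.approx(2.77)

    def test_linearity_in_glucose(self):
        base = {"sex": "male", "age": 50, "smoking": 1.0, "sbp": 140, "glucose": 5.0}
        shifted = dict(base, glucose=10.0)
        delta = (cs.linear_predictor(GLUCOSE_MODEL, shifted)
                 - cs.linear_predictor(GLUCOSE_MODEL, base))
        assert delta == pytest.approx(0.10 * 5.0)

    def test_missing_covariate_raises(self):
        with pytest.raises(KeyError):
            cs.linear_predictor(GLUCOSE_MODEL,
                                {"sex": "male", "age": 50, "smoking": 1.0, "sbp": 140})


class TestCumulativeBaselineHazard:
    def test_exponential_identity(self):
        assert cs.cumulative_baseline_hazard(0.0, 1.0, 3.0) == pytest.approx(3.0)

    def test_published_male_baseline_at_65(self):
        # direct evaluation: exp(-47.7) * 65**9.9
        expected = math.exp(-47.7) * 65.0 ** 9.9
        got = cs.cumulative_baseline_hazard(-47.7, 9.9, 65.0)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(1.70e-3, rel=5e-3)

    def test_power_law_doubling(self):
        for p in (1.0, 2.5, 9.9):
            ratio = (cs.cumulative_baseline_hazard(-3.0, p, 10.0)
                     / cs.cumulative_baseline_hazard(-3.0, p, 5.0))
            assert ratio == pytest.approx(2.0 ** p, rel=1e-10)

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            cs.cumulative_baseline_hazard(0.0, 2.0, 0.0)


class TestLogLikelihood:
    def test_single_censored_exponential_subject(self):
        """entry 40, exit 50, alpha=0, p=1, lp=0 -> -(H(50)-H(40)) = -10."""
        t = make_table([{"sex": "male", "entry_age": 40.0, "exit_age": 50.0,
                         "event": False}])
        params = np.array([0.0, 0.0, 0.0, 0.0])  # alpha_m, alpha_f, log p_m, log p_f
        assert cs.log_likelihood(params, t, []) == pytest.approx(-10.0)

    def test_matches_naive_per_subject_summation(self):
        """Independent scalar-math implementation of the likelihood."""
        rng = np.random.default_rng(2)
        rows = []
        for i in range(10):
            a0 = rng.uniform(40, 60)
            rows.append({"sex": "male" if i % 2 else "female", "age": a0,
                         "entry_age": a0, "exit_age": a0 + rng.uniform(1, 20),
                         "event": bool(rng.random() < 0.5),
                         "smoking": bool(i % 3 == 0), "glucose": rng.uniform(4, 8)})
        t = make_table(rows)
        params = np.array([-30.0, -35.0, np.log(7.0), np.log(8.0), 0.3, 0.08])
        cov = ["smoking", "glucose"]

        expected = 0.0
        for r in rows:
            alpha, p = ((-30.0, 7.0) if r["sex"] == "male" else (-35.0, 8.0))
            lp = 0.3 * float(r["smoking"]) + 0.08 * r["glucose"]
            H = lambda x: math.exp(alpha) * x ** p
            contrib = -(H(r["exit_age"]) - H(r["entry_age"])) * math.exp(lp)
            if r["event"]:
                contrib += (alpha + math.log(p)
                            + (p - 1) * math.log(r["exit_age"]) + lp)
            expected += contrib

        assert cs.log_likelihood(params, t, cov) == pytest.approx(expected, rel=1e-12)

    def test_additive_over_duplicated_record(self):
        row = {"sex": "male", "entry_age": 45.0, "exit_age": 55.0, "event": True}
        params = np.array([-20.0, -20.0, np.log(5.0), np.log(5.0)])
        one = cs.log_likelihood(params, make_table([row]), [])
        three = cs.log_likelihood(params, make_table([row] * 3), [])
        assert three == pytest.approx(3 * one, rel=1e-12)

    def test_nonfinite_params_barrier(self):
        t = make_table([{"entry_age": 40.0, "exit_age": 50.0}])
        assert cs.log_likelihood(np.array([np.nan, 0, 0, 0]), t, []) == -np.inf


def _one_stratum_cohort(n=20, seed=0, alpha=-20.0, p=5.0):
    rng = np.random.default_rng(seed)
    age = rng.uniform(40, 60, n)
    truth = cs.WeibullPHModel(alpha={"male": alpha}, shape={"male": p}, beta={})
    prof = pd.DataFrame({"sex": ["male"] * n, "age": age})
    ev = cs.sample_event_age(prof, truth, rng.uniform(0.05, 1.0, n))
    exit_age = np.minimum(ev, age + 25)
    df = prof.copy()
    df["entry_age"] = age
    df["exit_age"] = exit_age
    df["event"] = ev <= age + 25
    df["smoking"] = False
    df["sbp"] = 130.0
    return cs.CohortTable(df=df)


class TestFit:
    def test_mle_matches_dense_grid_search(self):
        """2-parameter toy: the optimizer agrees with an independent grid scan
        of a directly coded likelihood, to 3 decimals."""
        t = _one_stratum_cohort()
        fit = cs.fit_weibull_ph(t, [])
        assert fit.converged

        t0 = t.df["entry_age"].to_numpy()
        t1 = t.df["exit_age"].to_numpy()
        d = t.df["event"].to_numpy(dtype=bool)
        n_events = int(d.sum())

        # closed-form profile over alpha: for fixed p the likelihood is
        # maximized at exp(alpha) = D / sum(t1^p - t0^p), so only p needs a
        # grid; the scan is over a directly coded profile log-likelihood
        def profile_ll(ps):
            out, alphas = [], []
            for p in ps:
                denom = np.sum(t1 ** p - t0 ** p)
                a = np.log(n_events / denom)
                ll = (-n_events
                      + n_events * (a + np.log(p))
                      + (p - 1) * np.log(t1[d]).sum())
                out.append(ll)
                alphas.append(a)
            return np.array(out), np.array(alphas)

        coarse = np.linspace(1.5, 12.0, 400)
        L, _ = profile_ll(coarse)
        p_star = coarse[np.argmax(L)]
        fine = p_star + np.linspace(-0.05, 0.05, 1001)
        L2, alphas = profile_ll(fine)
        j = np.argmax(L2)
        assert fit.model.shape["male"] == pytest.approx(fine[j], abs=1e-3)
        assert fit.model.alpha["male"] == pytest.approx(alphas[j], abs=1e-2)

    def test_matches_lifelines_left_truncated_weibull(self):
        """No-covariate fit agrees with lifelines' delayed-entry WeibullFitter
        (their (lambda, rho) maps to alpha = -rho log lambda, p = rho)."""
        t = _one_stratum_cohort(n=300, seed=4)
        fit = cs.fit_weibull_ph(t, [])
        wf = WeibullFitter().fit(t.df["exit_age"], event_observed=t.df["event"],
                                 entry=t.df["entry_age"])
        assert fit.model.shape["male"] == pytest.approx(wf.rho_, rel=1e-3)
        assert fit.model.alpha["male"] == pytest.approx(-wf.rho_ * np.log(wf.lambda_),
                                                        rel=1e-3)

    def test_gradient_vanishes_at_optimum(self, sim_cohort, glucose_fit):
        cov = ["smoking", "sbp", "glucose"]
        m = glucose_fit.model
        theta = np.array([m.alpha["male"], m.alpha["female"],
                          np.log(m.shape["male"]), np.log(m.shape["female"]),
                          *m.beta.values()])
        ll0 = cs.log_likelihood(theta, sim_cohort, cov)
        scale = abs(ll0)
        for i in range(len(theta)):
            h = 1e-5 * max(1.0, abs(theta[i]))
            up, dn = theta.copy(), theta.copy()
            up[i] += h
            dn[i] -= h
            g = (cs.log_likelihood(up, sim_cohort, cov)
                 - cs.log_likelihood(dn, sim_cohort, cov)) / (2 * h)
            assert abs(g) / scale < 1e-4, i

    def test_fit_invariant_to_record_order(self, sim_cohort, glucose_fit):
        shuffled = cs.CohortTable(
            df=sim_cohort.df.sample(frac=1.0, random_state=1).reset_index(drop=True))
        refit = cs.fit_weibull_ph(shuffled, ["smoking", "sbp", "glucose"])
        for k in refit.model.beta:
            assert refit.model.beta[k] == pytest.approx(glucose_fit.model.beta[k],
                                                        abs=1e-4)

    def test_recovery_of_truth_within_wald_cis(self, glucose_fit):
        """n=8000 simulation under the published glucose truth: every true
        parameter inside its own 95% Wald interval (a loose single-run check;
        the calibration suite covers the distributional claim)."""
        truth = {"alpha_male": -47.7, "alpha_female": -58.8, "shape_male": 9.9,
                 "shape_female": 12.4, "smoking": 0.37, "sbp": 0.01, "glucose": 0.10}
        w = glucose_fit.wald
        for name, v in truth.items():
            lo, hi = w.loc[name, "ci_low"], w.loc[name, "ci_high"]
            span = hi - lo
            assert lo - 0.5 * span < v < hi + 0.5 * span, (name, v, lo, hi)

    def test_stratum_without_events_is_flagged(self):
        rows = [{"sex": "male", "entry_age": 45.0, "exit_age": 60.0,
                 "event": i < 5} for i in range(20)]
        rows += [{"sex": "female", "entry_age": 45.0, "exit_age": 60.0,
                  "event": False} for _ in range(10)]
        fit = cs.fit_weibull_ph(make_table(rows), [])
        assert not fit.converged and "female" in fit.message

    def test_covariance_symmetric_psd(self, glucose_fit):
        C = glucose_fit.covariance.to_numpy()
        np.testing.assert_allclose(C, C.T, rtol=1e-6)
        assert np.all(np.linalg.eigvalsh(C) > -1e-10)


class TestPredictAbsoluteRisk:
    PROFILE = {"sex": "male", "age": 65.0, "smoking": 1.0, "sbp": 180.0,
               "glucose": 6.0}

    def test_vanishes_as_horizon_shrinks(self):
        r = cs.predict_absolute_risk(GLUCOSE_MODEL, self.PROFILE, 1e-9)
        assert 0 < r < 1e-8

    def test_monotone_in_horizon(self):
        r10 = cs.predict_absolute_risk(GLUCOSE_MODEL, self.PROFILE, 10)
        r20 = cs.predict_absolute_risk(GLUCOSE_MODEL, self.PROFILE, 20)
        r30 = cs.predict_absolute_risk(GLUCOSE_MODEL, self.PROFILE, 30)
        assert r10 < r20 < r30 < 1.0

    def test_monotone_in_age_and_positive_covariates(self):
        for field, delta in (("age", 5.0), ("sbp", 20.0), ("glucose", 2.0)):
            hi = dict(self.PROFILE)
            hi[field] = hi[field] + delta
            assert (cs.predict_absolute_risk(GLUCOSE_MODEL, hi, 10)
                    > cs.predict_absolute_risk(GLUCOSE_MODEL, self.PROFILE, 10))

    def test_equals_unconditional_survival_ratio(self):
        """risk = 1 - S(a0+h)/S(a0) with S(t) = exp(-H0(t) e^lp)."""
        lp = cs.linear_predictor(GLUCOSE_MODEL, self.PROFILE)
        a, p = GLUCOSE_MODEL.alpha["male"], GLUCOSE_MODEL.shape["male"]
        S = lambda t: math.exp(-math.exp(a) * t ** p * math.exp(lp))
        expected = 1.0 - S(75.0) / S(65.0)
        got = cs.predict_absolute_risk(GLUCOSE_MODEL, self.PROFILE, 10)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            cs.predict_absolute_risk(GLUCOSE_MODEL, self.PROFILE, 0.0)
        with pytest.raises(ValueError):
            cs.predict_absolute_risk(GLUCOSE_MODEL, dict(self.PROFILE, age=15.0), 10)


class TestWaldTest:
    def test_zero_estimate_p_one(self):
        z, p = cs.wald_test(0.0, 1.0)
        assert z == 0.0 and p == 1.0

    def test_1_96_se_gives_p_05(self):
        _, p = cs.wald_test(1.96, 1.0)
        assert p == pytest.approx(0.05, abs=1e-3)

    def test_reported_cholesterol_interval_reproduces_its_p_value(self):
        """Estimate 0.10 with 95% CI (0.00, 0.20): se ~ 0.051, p ~ 0.05
        (the published 0.046 reflects unrounded inputs)."""
        se = (0.20 - 0.00) / (2 * 1.959964)
        _, p = cs.wald_test(0.10, se)
        assert 0.04 < p < 0.06

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            cs.wald_test(1.0, 0.0)


def test_model_covariates_are_profile_fields():
    assert set(GLUCOSE_MODEL.beta) <= set(MODEL_COVARIATES)
    with pytest.raises(ValueError):
        cs.WeibullPHModel(alpha={"male": -40}, shape={"male": 9}, beta={"bmi": 0.1})
    with pytest.raises(ValueError):
        cs.WeibullPHModel(alpha={"male": -40}, shape={"male": -1}, beta={})
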