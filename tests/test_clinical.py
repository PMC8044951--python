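"""Clinical validation statistics: dichotomization, chi-square association,
Kaplan-Meier, log-rank, and Cox proportional hazards."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from netprio import cox_fit, dichotomize, km_fit, logrank_test, pearson_chi2
from netprio.clinical import _cox_loglik
from netprio.published import CLINICAL_TABLES
from netprio.sim import SimConfig, simulate_clinical, _build_truth


class TestDichotomize:
    def test_median_split(self):
        labels = dichotomize([1, 2, 3, 4])
        assert list(labels) == ["Low", "Low", "High", "High"]

    def test_value_at_median_goes_low(self):
        labels = dichotomize([1, 2, 3])
        assert list(labels) == ["Low", "Low", "High"]

    def test_identical_values_warn_all_low(self):
        with pytest.warns(UserWarning):
            labels = dichotomize([5, 5, 5])
        assert (labels == "Low").all()

    def test_simulated_h_scores_match_sort_oracle(self):
        rng = np.random.default_rng(6)
        scores = rng.uniform(0, 100, 90)
        labels = dichotomize(scores)
        med = np.median(np.sort(scores))
        expected = np.where(scores > med, "High", "Low")
        assert (labels == expected).all()
        assert (labels == "High").sum() + (labels == "Low").sum() == 90


class TestPearsonChi2:
    def test_histologic_differentiation_table(self):
        res = pearson_chi2(CLINICAL_TABLES["histologic_differentiation"]["counts"])
        assert res.df == 2
        assert res.p == pytest.approx(0.032, abs=5e-4)

    def test_gender_table(self):
        res = pearson_chi2(CLINICAL_TABLES["gender"]["counts"])
        assert res.df == 1
        assert res.p == pytest.approx(0.808, abs=5e-4)

    def test_identical_row_distributions_give_zero(self):
        res = pearson_chi2([[10, 20], [5, 10]])
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_permutation_and_transpose_invariance(self):
        t = np.array([[4, 14, 3], [5, 34, 30]])
        base = pearson_chi2(t).chi2
        assert pearson_chi2(t.T).chi2 == pytest.approx(base)
        assert pearson_chi2(t[::-1]).chi2 == pytest.approx(base)
        assert pearson_chi2(t[:, ::-1]).chi2 == pytest.approx(base)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            pearson_chi2([[0, 0], [3, 4]])


class TestKaplanMeier:
    def test_all_censored_curve_stays_at_one(self):
        c = km_fit([3, 5, 9], [0, 0, 0])
        assert c.event_times.size == 0
        assert c.median is None
        assert c.at(100) == 1.0

    def test_two_events_hand_values(self):
        c = km_fit([1, 2], [1, 1])
        np.testing.assert_allclose(c.survival, [0.5, 0.0])
        assert c.median == 1.0

    def test_censoring_between_events(self):
        c = km_fit([1, 2, 3], [1, 0, 1])
        np.testing.assert_allclose(c.event_times, [1.0, 3.0])
        np.testing.assert_allclose(c.survival, [2 / 3, 0.0])
        assert c.at(2) == pytest.approx(2 / 3)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(8)
        t = rng.exponential(5, 40).round(2)
        c = km_fit(t, np.ones_like(t, dtype=int))
        for u in [1.0, 3.0, 7.0]:
            assert c.at(u) == pytest.approx((t > u).mean())

    def test_nonincreasing_steps(self):
        rng = np.random.default_rng(9)
        t = rng.exponential(5, 50)
        e = rng.integers(0, 2, 50)
        c = km_fit(t, e)
        assert (np.diff(c.survival) <= 1e-12).all()

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            km_fit([0.0, 1.0], [1, 1])


class TestLogrank:
    def test_identical_groups_give_null(self):
        t = [1, 2, 3, 1, 2, 3]
        e = [1, 1, 0, 1, 1, 0]
        g = ["A"] * 3 + ["B"] * 3
        chi2, df, p = logrank_test(g, t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_tabulated_two_groups(self):
        # A dies at 1, 2; B dies at 3, 4: tabulate O/E/V over the 4 times
        g = ["A", "A", "B", "B"]
        t = [1.0, 2.0, 3.0, 4.0]
        e = [1, 1, 1, 1]
        # t=1: nA=2, nB=2 -> E_A=.5, V=.25 ; t=2: nA=1,nB=2 -> E_A=1/3, V=2/9
        # t=3: nA=0 -> E_A=0, V=0 ; t=4: same
        o_a, e_a, v = 2.0, 0.5 + 1 / 3, 0.25 + 2 / 9
        expected = (o_a - e_a) ** 2 / v
        chi2, df, p = logrank_test(g, t, e)
        assert df == 1
        assert chi2 == pytest.approx(expected, abs=1e-12)

    def test_matches_lifelines(self):
        from lifelines.statistics import multivariate_logrank_test

        rng = np.random.default_rng(12)
        t = rng.exponential(10, 60)
        e = rng.integers(0, 2, 60)
        g = rng.integers(0, 3, 60)
        chi2, df, p = logrank_test(g, t, e)
        ref = multivariate_logrank_test(t, g, e)
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test(["A", "A"], [1, 2], [1, 1])

    def test_equals_cox_score_test_on_binary_covariate(self):
        rng = np.random.default_rng(0)
        checked = 0
        for _ in range(20):
            n = 30
            t = rng.exponential(10, n)  # continuous => no ties
            e = rng.integers(0, 2, n)
            x = rng.integers(0, 2, n)
            if e.sum() < 2 or x.std() == 0:
                continue
            chi2, _, _ = logrank_test(x, t, e)
            X = (x - x.mean()).reshape(-1, 1).astype(float)
            _, score, info = _cox_loglik(np.zeros(1), X, t, e, "breslow")
            assert chi2 == pytest.approx(float(score[0] ** 2 / info[0, 0]), abs=1e-6)
            checked += 1
        assert checked >= 15


class TestCox:
    def _toy(self):
        t = np.array([2.0, 4.0, 3.0, 5.0, 7.0, 9.0])
        e = np.array([1, 1, 1, 1, 1, 0])
        x = np.array([1.0, 1.0, 0.0, 1.0, 0.0, 0.0])
        return t, e, x

    def test_identical_groups_give_null_hr(self):
        t = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        e = np.array([1, 1, 0, 1, 1, 0])
        x = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
        res = cox_fit(pd.DataFrame({"grp": x}), t, e)
        assert res.beta["grp"] == pytest.approx(0.0, abs=1e-6)
        assert res.hr["grp"] == pytest.approx(1.0, abs=1e-6)

    def test_matches_brute_force_partial_likelihood(self):
        t, e, x = self._toy()
        res = cox_fit(pd.DataFrame({"x": x}), t, e)
        xc = (x - x.mean()).reshape(-1, 1)

        def nll(b):
            return -_cox_loglik(np.array([b]), xc, t, e, "breslow")[0]

        brute = minimize_scalar(nll, bounds=(-10, 10), method="bounded",
                                options={"xatol": 1e-10}).x
        assert res.beta["x"] == pytest.approx(brute, abs=1e-4)

    def test_efron_matches_lifelines(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(3)
        n = 80
        x = rng.integers(0, 2, n).astype(float)
        t = np.ceil(rng.exponential(10, n) / np.exp(0.7 * x))  # ties on purpose
        e = rng.integers(0, 2, n)
        res = cox_fit(pd.DataFrame({"x": x}), t, e, ties="efron")
        cph = CoxPHFitter().fit(pd.DataFrame({"t": t, "e": e, "x": x}), "t", "e")
        assert res.beta["x"] == pytest.approx(cph.params_["x"], abs=1e-3)
        assert res.summary.loc["x", "se"] == pytest.approx(
            cph.standard_errors_["x"], abs=1e-3
        )

    def test_ci_contains_hr_and_positive(self):
        t, e, x = self._toy()
        res = cox_fit(pd.DataFrame({"x": x}), t, e)
        row = res.summary.loc["x"]
        assert 0 < row["ci_low"] <= row["hr"] <= row["ci_high"]

    def test_constant_covariate_rejected(self):
        t, e, _ = self._toy()
        with pytest.raises(ValueError, match="constant"):
            cox_fit(pd.DataFrame({"x": np.ones(6)}), t, e)

    def test_null_marker_estimates_center_at_zero(self):
        betas = []
        for seed in range(25):
            cfg = SimConfig(seed=seed, n_patients=500, true_hr=1.0)
            truth = _build_truth(cfg)
            clin = simulate_clinical(cfg, truth)
            labels = dichotomize(clin["marker"].to_numpy())
            res = cox_fit(
                pd.DataFrame({"hi": (labels == "High").astype(float)}, index=clin.index),
                clin["time_months"], clin["event"],
            )
            betas.append(res.beta["hi"])
        assert abs(np.mean(betas)) < 0.05

    def test_multivariable_enter_method_fits_all_covariates(self):
        cfg = SimConfig(seed=2, n_patients=200)
        truth = _build_truth(cfg)
        clin = simulate_clinical(cfg, truth)
        labels = dichotomize(clin["marker"].to_numpy())
        design = pd.DataFrame(
            {
                "marker_high": (labels == "High").astype(float),
                "tnm_stage": clin["tnm_stage"].astype(float),
                "differentiation": clin["differentiation"].astype(float),
            },
            index=clin.index,
        )
        res = cox_fit(design, clin["time_months"], clin["event"])
        assert list(res.summary.index) == ["marker_high", "tnm_stage", "differentiation"]
        assert np.isfinite(res.summary[["beta", "se", "p"]].to_numpy()).all()
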