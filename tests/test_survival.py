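"""Kaplan–Meier, log-rank, Cox partial likelihood and power formula."""
import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from lnstage import (
    SurvivalError,
    cox_fit,
    cox_score_test,
    encode_base_covariates,
    fit_base_model,
    km_estimate,
    logrank_power,
    logrank_test,
)
from conftest import partial_loglik_1d, random_survival_instance


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        curve = km_estimate([2.0, 3.0, 7.0], [1, 1, 1])
        np.testing.assert_allclose(curve.survival, [2 / 3, 1 / 3, 0.0])

    def test_hand_product_limit_with_censoring(self):
        curve = km_estimate([2.0, 3.0, 5.0, 7.0], [1, 1, 0, 1])
        np.testing.assert_allclose(curve.survival, [0.75, 0.5, 0.0])
        np.testing.assert_array_equal(curve.at_risk, [4, 3, 1])

    def test_all_censored_curve_stays_at_one(self):
        curve = km_estimate([5.0, 6.0], [0, 0])
        assert curve.times.size == 0
        assert curve.censor_times.tolist() == [5.0, 6.0]

    def test_empty_and_nonpositive_rejected(self):
        with pytest.raises(SurvivalError):
            km_estimate([], [])
        with pytest.raises(SurvivalError):
            km_estimate([0.0, 1.0], [1, 1])


class TestLogrank:
    def test_identical_groups_give_zero(self):
        t = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        e = [1, 1, 0, 1, 1, 0]
        g = ["a"] * 3 + ["b"] * 3
        res = logrank_test(t, e, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.df == 1

    def test_hand_hypergeometric_four_subjects(self):
        # A: event at 1, censored at 2; B: event at 3, censored at 4.
        # Event@1: O-E = 1 - 2/4, V = .5*.5;  Event@3: A no longer at risk.
        res = logrank_test([1, 2, 3, 4], [1, 0, 1, 0], ["A", "A", "B", "B"])
        assert res.statistic == pytest.approx((0.5) ** 2 / 0.25, abs=1e-10)

    def test_three_groups_df(self):
        res = logrank_test([1, 2, 3, 4, 5, 6], [1] * 6, ["a", "a", "b", "b", "c", "c"])
        assert res.df == 2

    def test_single_group_rejected(self):
        with pytest.raises(SurvivalError):
            logrank_test([1, 2], [1, 1], ["a", "a"])


class TestCoxFit:
    def test_four_subject_hand_likelihood(self):
        """beta-hat equals the maximiser of a/(2a+2) * 1/(a+2) * a/(a+1)."""
        X = pd.DataFrame({"x": [1, 0, 1, 0]})
        fit = cox_fit(X, [1.0, 2.0, 3.0, 4.0], [1, 1, 1, 0])

        def neg_pl(beta):
            a = np.exp(beta)
            return -np.log(a / (2 * a + 2) * 1 / (a + 2) * a / (a + 1))

        oracle = minimize_scalar(neg_pl, bounds=(-5, 5), method="bounded",
                                 options={"xatol": 1e-12})
        assert fit.coef[0] == pytest.approx(oracle.x, abs=1e-6)

    def test_matches_1d_brute_force_on_random_cohorts(self, rng):
        """100 random tie-free single-covariate fits vs direct maximisation."""
        for _ in range(100):
            n = int(rng.integers(5, 15))
            x, times, events = random_survival_instance(rng, n, score_levels=2)
            if len(np.unique(x)) < 2:
                continue
            fit = cox_fit(pd.DataFrame({"x": x}), times, events)
            if not fit.converged:
                continue  # separation: flagged, not comparable to the oracle
            oracle = minimize_scalar(
                lambda b: -partial_loglik_1d(b, times, events, x),
                bounds=(-15, 15), method="bounded", options={"xatol": 1e-10},
            )
            assert fit.coef[0] == pytest.approx(oracle.x, abs=1e-6)

    def test_duplicated_data_same_beta_se_shrinks_sqrt2(self, rng):
        """Row duplication: identical estimate, SE / sqrt(2) (Breslow exact)."""
        x, times, events = random_survival_instance(rng, 30, score_levels=2)
        X = pd.DataFrame({"x": x})
        single = cox_fit(X, times, events, ties="breslow")
        double = cox_fit(
            pd.concat([X, X], ignore_index=True),
            np.concatenate([times, times]),
            np.concatenate([events, events]),
            ties="breslow",
        )
        assert double.coef[0] == pytest.approx(single.coef[0], abs=1e-6)
        assert double.se[0] == pytest.approx(single.se[0] / np.sqrt(2), abs=1e-6)

    def test_score_test_equals_logrank_on_tie_free_data(self, rng):
        x, times, events = random_survival_instance(rng, 40, score_levels=2)
        if len(np.unique(x)) < 2:
            x[0] = 1 - x[0]
        lr = logrank_test(times, events, x.astype(int))
        sc = cox_score_test(times, events, x)
        assert sc.statistic == pytest.approx(lr.statistic, abs=1e-8)

    def test_efron_agrees_with_lifelines_on_tied_data(self, rng):
        """Independent cross-check of the tie handling."""
        from lifelines import CoxPHFitter

        x, times, events = random_survival_instance(rng, 60, tie_free=False)
        df = pd.DataFrame({"x": x, "T": times, "E": events})
        fit = cox_fit(df[["x"]], times, events, ties="efron")
        cph = CoxPHFitter().fit(df, "T", "E")
        assert fit.coef[0] == pytest.approx(cph.params_.iloc[0], abs=1e-5)
        assert fit.se[0] == pytest.approx(cph.standard_errors_.iloc[0], abs=1e-5)

    def test_constant_covariate_dropped_and_null_loglik(self):
        X = pd.DataFrame({"zero": [0, 0, 0, 0], "x": [1, 0, 1, 0]})
        fit = cox_fit(X, [1.0, 2.0, 3.0, 4.0], [1, 1, 1, 0])
        assert fit.dropped == ["zero"]
        only_const = pd.DataFrame({"zero": [0, 0, 0, 0]})
        with pytest.raises(SurvivalError):
            cox_fit(only_const, [1.0, 2.0, 3.0, 4.0], [1, 1, 1, 0])

    def test_no_events_rejected(self):
        with pytest.raises(SurvivalError, match="no events"):
            cox_fit(pd.DataFrame({"x": [1, 0]}), [1.0, 2.0], [0, 0])

    def test_separation_flagged_not_silent(self):
        # covariate perfectly orders deaths before censorings
        X = pd.DataFrame({"x": [1, 1, 1, 0, 0, 0]})
        fit = cox_fit(X, [1.0, 2.0, 3.0, 10.0, 11.0, 12.0], [1, 1, 1, 0, 0, 0])
        assert not fit.converged
        assert fit.warnings

    def test_row_permutation_invariance(self, default_cohort):
        fit = fit_base_model(default_cohort)
        shuffled = default_cohort.copy()
        shuffled.df = shuffled.df.sample(frac=1.0, random_state=9).reset_index(drop=True)
        fit2 = fit_base_model(shuffled)
        np.testing.assert_allclose(fit.coef, fit2.coef, atol=1e-9)

    def test_base_model_terms_and_encoding(self, default_cohort):
        X, meta = encode_base_covariates(default_cohort)
        assert list(X.columns) == [
            "age_ge70", "male", "size_ge_median", "grade_34", "t_34", "rectum",
        ]
        assert X.isin([0, 1]).all().all()
        # median computed on the analysis cohort before dichotomisation
        assert meta["size_median_mm"] == default_cohort.df["size_mm"].median()
        fit = fit_base_model(default_cohort)
        assert fit.converged and len(fit.terms) == 6
        assert np.all(fit.ci_low < fit.hr) and np.all(fit.hr < fit.ci_high)


class TestLogrankPower:
    def test_schoenfeld_events(self):
        assert logrank_power(1.5, 0.05, 0.90, 0.5)["events"] == 256
        assert logrank_power(2.0, 0.05, 0.90, 0.5)["events"] == 88

    def test_monotone_in_alpha(self):
        alphas = [0.01, 0.05, 0.10, 0.20]
        d = [logrank_power(1.5, a, 0.5, 0.5)["events_exact"] for a in alphas]
        assert all(x > y for x, y in zip(d, d[1:]))

    def test_total_n_from_event_fraction(self):
        out = logrank_power(1.5, 0.05, 0.90, 0.5, event_fraction=0.5)
        assert out["total_n"] == int(np.ceil(out["events_exact"] / 0.5))

    def test_null_hr_rejected(self):
        with pytest.raises(SurvivalError):
            logrank_power(1.0)
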