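"""Harrell's C, jackknife Delta-C, FDR, landmark AUC, Spearman."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lnstage import (
    DiscriminationError,
    fdr_adjust,
    harrell_c,
    harrell_c_ci,
    jackknife_delta_c,
    landmark_auc,
    spearman_rho,
)
from conftest import brute_force_c, brute_force_delta_c, random_survival_instance


class TestHarrellC:
    def test_perfect_ranking(self):
        assert harrell_c([3, 2, 1], [1, 2, 3], [1, 1, 1]).c_index == 1.0

    def test_hand_enumerated_mixed_censoring(self):
        res = harrell_c([2, 1, 3], [1, 2, 3], [1, 0, 1])
        assert res.c_index == 0.5
        assert res.n_comparable == 2

    def test_complete_score_ties(self):
        res = harrell_c([1, 1, 1], [1, 2, 3], [1, 1, 1])
        assert res.c_index == 0.5
        assert res.n_tied_score == res.n_comparable == 3

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(DiscriminationError):
            harrell_c([1, 2], [1.0, 2.0], [0, 0])

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 13))
            scores, times, events = random_survival_instance(
                rng, n, tie_free=bool(rng.integers(2)), score_levels=4
            )
            try:
                expected = brute_force_c(scores, times, events)
            except ValueError:
                continue
            assert harrell_c(scores, times, events).c_index == pytest.approx(
                expected, abs=1e-14
            )

    def test_invariant_to_monotone_score_transform(self, rng):
        scores, times, events = random_survival_instance(rng, 40)
        a = harrell_c(scores, times, events).c_index
        b = harrell_c(np.exp(2 * scores) + 7, times, events).c_index
        assert a == pytest.approx(b, abs=1e-14)

    def test_score_negation_complements_c(self, rng):
        scores, times, events = random_survival_instance(rng, 40)
        a = harrell_c(scores, times, events).c_index
        b = harrell_c(-scores, times, events).c_index
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_jackknife_ci_brackets_estimate(self, rng):
        scores, times, events = random_survival_instance(rng, 60)
        res = harrell_c_ci(scores, times, events)
        assert res.ci_low < res.c_index < res.ci_high


class TestJackknifeDeltaC:
    def test_self_comparison_is_identical(self, rng):
        scores, times, events = random_survival_instance(rng, 20)
        res = jackknife_delta_c(scores, scores, times, events)
        assert res.delta_c == 0.0 and res.se == 0.0 and res.note == "identical"
        assert res.p_value is None

    def test_matches_full_recompute_oracle_small_cohorts(self, rng):
        """Exact agreement with the O(n^3) leave-one-out oracle, n <= 12."""
        checked = 0
        while checked < 60:
            n = int(rng.integers(5, 13))
            sa, times, events = random_survival_instance(
                rng, n, tie_free=bool(rng.integers(2)), score_levels=4
            )
            sb = rng.normal(size=n)
            try:
                delta, se = brute_force_delta_c(sa, sb, times, events)
            except ValueError:
                continue  # a deletion kills all comparable pairs
            res = jackknife_delta_c(sa, sb, times, events)
            assert res.delta_c == pytest.approx(delta, abs=1e-12)
            assert res.se == pytest.approx(se, abs=1e-12)
            checked += 1

    def test_swap_antisymmetry(self, rng):
        sa, times, events = random_survival_instance(rng, 25)
        sb = rng.normal(size=25)
        ab = jackknife_delta_c(sa, sb, times, events)
        ba = jackknife_delta_c(sb, sa, times, events)
        assert ab.delta_c == pytest.approx(-ba.delta_c, abs=1e-14)
        assert ab.se == pytest.approx(ba.se, abs=1e-14)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(DiscriminationError):
            jackknife_delta_c([1, 2], [2, 1], [1.0, 2.0], [1, 1])


class TestFDR:
    def test_hand_step_up(self):
        np.testing.assert_allclose(
            fdr_adjust([0.005, 0.03, 0.04], m=3), [0.015, 0.04, 0.04]
        )

    def test_single_and_equal_p_unchanged(self):
        assert fdr_adjust([0.03])[0] == pytest.approx(0.03)
        np.testing.assert_allclose(fdr_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_family_larger_than_reported(self):
        np.testing.assert_allclose(fdr_adjust([0.01, 0.04], m=4), [0.04, 0.08])

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(25)
        _, expected, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(fdr_adjust(p), expected, atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=20))
    @settings(max_examples=200, derandomize=True)
    def test_monotone_and_dominates_raw(self, ps):
        adj = fdr_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestLandmarkAUC:
    def test_perfect_and_null_separation(self):
        t = [1.0, 2.0, 20.0, 30.0]
        e = [1, 1, 0, 0]
        assert landmark_auc([9, 8, 1, 2], t, e, horizon=10).auc == 1.0
        assert landmark_auc([5, 5, 5, 5], t, e, horizon=10).auc == 0.5

    def test_brute_force_pair_count(self):
        # 3 cases vs 3 controls, one crossing pair -> 8/9
        scores = [5, 4, 2, 3, 1, 0]
        t = [1, 2, 3, 20, 21, 22]
        e = [1, 1, 1, 0, 0, 0]
        res = landmark_auc(scores, t, e, horizon=10)
        assert res.auc == pytest.approx(8 / 9)
        assert (res.n_cases, res.n_controls) == (3, 3)

    def test_censored_before_horizon_excluded(self):
        res = landmark_auc([1, 2, 3, 4], [5.0, 9.0, 20.0, 30.0], [1, 0, 0, 1], 10)
        assert res.n_excluded == 1 and res.n_cases == 1 and res.n_controls == 2

    def test_equals_harrell_c_on_uncensored_dichotomy(self, rng):
        """With no censoring, landmark AUC is Harrell's C on the
        dichotomised outcome."""
        n = 40
        scores = rng.normal(size=n)
        dead_by_h = rng.random(n) < 0.5
        dead_by_h[:2] = [True, False]
        times = np.where(dead_by_h, 5.0, 20.0)
        events = np.ones(n, dtype=int)
        auc = landmark_auc(scores, times, events, horizon=10).auc
        c = harrell_c(scores, np.where(dead_by_h, 1.0, 2.0),
                      np.where(dead_by_h, 1, 0)).c_index
        assert auc == pytest.approx(c, abs=1e-12)

    def test_no_cases_rejected(self):
        with pytest.raises(DiscriminationError):
            landmark_auc([1, 2], [20.0, 30.0], [0, 0], 10)


class TestSpearman:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ([1, 2, 3, 4], [10, 20, 30, 40], 1.0),
            ([1, 2, 3, 4], [40, 30, 20, 10], -1.0),
            ([1, 2, 3, 4], [1, 3, 2, 4], 0.8),
        ],
    )
    def test_hand_values(self, x, y, expected):
        assert spearman_rho(x, y) == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(DiscriminationError):
            spearman_rho([1, 1, 1], [1, 2, 3])
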