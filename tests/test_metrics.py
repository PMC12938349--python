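"""Evaluation statistics against hand computations and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathomil.losses import SurvivalLabel
from pathomil.metrics import (
    ContingencyTable,
    assign_risk_groups,
    bootstrap_compare,
    chi_square_independence,
    harrell_c,
    km_estimate,
    kruskal_wallis,
    roc_auc,
    tertile_stratify,
    threshold_metrics,
    time_dependent_auc,
    trials_summary,
)


def pairwise_auc_oracle(scores, labels):
    """Probability a random positive outranks a random negative; ties 1/2."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def harrell_oracle(risks, times, events):
    """O(n²) enumeration of Harrell-comparable pairs (tie-free times)."""
    num = den = 0.0
    n = len(risks)
    for i in range(n):
        for j in range(n):
            if times[i] < times[j] and events[i] == 1:
                den += 1
                if risks[i] > risks[j]:
                    num += 1
                elif risks[i] == risks[j]:
                    num += 0.5
    return num / den


class TestRocAuc:
    def test_perfect_separation(self):
        s = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1], ci=False)
        assert s.point == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1], ci=False).point == 0.5

    def test_enumerated_example(self):
        s = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1], ci=False)
        assert s.point == 0.75

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="one class"):
            roc_auc([0.1, 0.2], [1, 1], ci=False)

    def test_equals_pairwise_oracle_on_random_inputs(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 51))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            scores = np.round(rng.random(n), 2)  # induce ties
            got = roc_auc(scores, labels, ci=False).point
            assert got == pytest.approx(
                pairwise_auc_oracle(scores, labels), abs=1e-12
            )

    def test_bootstrap_ci_is_deterministic_given_seed(self, rng):
        scores = rng.random(40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        a = roc_auc(scores, labels, n_boot=200, seed=5)
        b = roc_auc(scores, labels, n_boot=200, seed=5)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)


class TestThresholdMetrics:
    def test_perfect_classifier(self):
        m = threshold_metrics([0.1, 0.9, 0.2, 0.8], [0, 1, 0, 1], 0.5)
        assert all(v == 1.0 for v in m.values())

    def test_all_predicted_positive(self):
        m = threshold_metrics([0.9] * 10, [1] * 6 + [0] * 4, 0.5)
        assert m["recall"] == 1.0
        assert m["specificity"] == 0.0
        assert m["precision"] == pytest.approx(0.6)

    def test_confusion_fixture(self):
        # TP=3, FP=1, FN=1, TN=5
        scores = [0.9, 0.9, 0.9, 0.1, 0.9, 0.1, 0.1, 0.1, 0.1, 0.1]
        labels = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        m = threshold_metrics(scores, labels, 0.5)
        assert m["precision"] == pytest.approx(0.75)
        assert m["recall"] == pytest.approx(0.75)
        assert m["f1"] == pytest.approx(0.75)
        assert m["specificity"] == pytest.approx(5 / 6)


class TestHarrellC:
    def test_reverse_ordered_risks_give_one(self):
        labels = [SurvivalLabel(t, 1) for t in (1, 2, 3, 4)]
        assert harrell_c([4, 3, 2, 1], labels).point == 1.0

    def test_constant_risks_give_half(self):
        labels = [SurvivalLabel(t, 1) for t in (1, 2, 3, 4)]
        assert harrell_c([1, 1, 1, 1], labels).point == 0.5

    def test_matches_brute_force_oracle_with_censoring(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 30))
            times = rng.exponential(10, n) + 0.01  # continuous, tie-free a.s.
            events = rng.integers(0, 2, n)
            if events[np.argsort(times)][:-1].sum() == 0:
                continue
            risks = rng.standard_normal(n)
            got = harrell_c(risks, [SurvivalLabel(t, int(e))
                                    for t, e in zip(times, events)]).point
            assert got == pytest.approx(
                harrell_oracle(risks, times, events), abs=1e-12
            )

    def test_negated_risks_complement_concordance(self, rng):
        times = rng.exponential(5, 20) + 0.01
        events = np.ones(20, dtype=int)
        risks = rng.standard_normal(20)
        labels = [SurvivalLabel(t, 1) for t in times]
        c1 = harrell_c(risks, labels).point
        c2 = harrell_c(-risks, labels).point
        assert c1 + c2 == pytest.approx(1.0, abs=1e-12)


class TestTimeDependentAuc:
    def test_perfect_risk_ordering_gives_one(self):
        times = np.linspace(1, 20, 20)
        labels = [SurvivalLabel(t, 1) for t in times]
        s = time_dependent_auc(-times, labels, horizon=10.0)
        assert s.point == pytest.approx(1.0)

    def test_no_censoring_reduces_to_plain_auc(self, rng):
        times = rng.exponential(10, 80) + 0.1
        risks = rng.standard_normal(80)
        h = float(np.median(times))
        labels = [SurvivalLabel(t, 1) for t in times]
        td = time_dependent_auc(risks, labels, h).point
        plain = roc_auc(risks, (times <= h).astype(int), ci=False).point
        assert td == pytest.approx(plain, abs=1e-10)

    def test_uninformative_risks_near_half_at_large_n(self):
        rng = np.random.default_rng(42)
        n = 2000
        times = rng.exponential(10, n) + 0.1
        cens = rng.exponential(25, n)
        obs = np.minimum(times, cens)
        events = (times <= cens).astype(int)
        risks = rng.standard_normal(n)
        labels = [SurvivalLabel(t, int(e)) for t, e in zip(obs, events)]
        s = time_dependent_auc(risks, labels, horizon=8.0)
        assert abs(s.point - 0.5) < 0.03

    def test_no_events_by_horizon_raises(self):
        labels = [SurvivalLabel(10.0, 1), SurvivalLabel(12.0, 0)]
        with pytest.raises(ValueError, match="no events"):
            time_dependent_auc([1.0, 0.0], labels, horizon=5.0)


class TestKaplanMeier:
    def test_uncensored_equals_empirical_survival(self):
        labels = [SurvivalLabel(t, 1) for t in (1, 2, 3, 4)]
        curve, _ = km_estimate(labels)
        assert curve.survival_at(2.5) == pytest.approx(0.5)
        assert curve.median == 2.0

    def test_all_censored_curve_stays_at_one(self):
        labels = [SurvivalLabel(t, 0) for t in (1, 2, 3)]
        curve, _ = km_estimate(labels)
        assert np.all(curve.survival == 1.0)
        assert not curve.median_reached

    def test_textbook_six_subject_fixture(self):
        # times 1, 2+, 3, 4+, 5, 6 (+ = censored): hand-computed product limit
        labels = [
            SurvivalLabel(1, 1), SurvivalLabel(2, 0), SurvivalLabel(3, 1),
            SurvivalLabel(4, 0), SurvivalLabel(5, 1), SurvivalLabel(6, 1),
        ]
        curve, horizons = km_estimate(labels, horizons=(3.5,))
        assert curve.survival_at(1) == pytest.approx(5 / 6)
        assert curve.survival_at(3) == pytest.approx(5 / 6 * 3 / 4)
        assert curve.survival_at(5) == pytest.approx(5 / 6 * 3 / 4 * 1 / 2)
        assert curve.survival_at(6) == pytest.approx(0.0)
        assert curve.median == 5.0
        assert horizons[3.5].point == pytest.approx(0.625)
        assert horizons[3.5].ci_low <= 0.625 <= horizons[3.5].ci_high


class TestTertiles:
    def test_one_to_nine_cutpoints_and_group_sizes(self):
        th = tertile_stratify(np.arange(1, 10))
        assert th.q1 == pytest.approx(11 / 3)
        assert th.q2 == pytest.approx(19 / 3)
        groups = assign_risk_groups(np.arange(1, 10), th)
        assert [groups.count(g) for g in ("low", "intermediate", "high")] == \
            [3, 3, 3]

    def test_score_below_training_range_goes_low(self):
        th = tertile_stratify(np.arange(1, 10))
        assert th.assign(-100.0) == "low"

    def test_degenerate_scores_raise(self):
        with pytest.raises(ValueError, match="degenerate"):
            tertile_stratify([1.0, 1.0, 1.0, 2.0])

    @given(st.integers(0, 1000))
    @settings(deadline=None, max_examples=30)
    def test_group_sizes_balanced_for_distinct_divisible_n(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.permutation(rng.standard_normal(30))
        groups = assign_risk_groups(scores, tertile_stratify(scores))
        sizes = [groups.count(g) for g in ("low", "intermediate", "high")]
        assert max(sizes) - min(sizes) <= 1

    def test_monotone_rescaling_preserves_assignments(self, rng):
        scores = rng.standard_normal(40)
        test = rng.standard_normal(25)
        th1 = tertile_stratify(scores)
        th2 = tertile_stratify(np.exp(scores))
        assert assign_risk_groups(test, th1) == \
            assign_risk_groups(np.exp(test), th2)


class TestChiSquare:
    def test_proportional_table_gives_zero_statistic(self):
        stat, df, p = chi_square_independence(np.array([[10, 20], [5, 10]]))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_diagonal_table_closed_form(self):
        stat, df, p = chi_square_independence(np.array([[10, 0], [0, 10]]))
        assert stat == pytest.approx(20.0)
        assert df == 1
        assert p == pytest.approx(7.74e-6, rel=1e-2)

    def test_development_cohort_stage_row(self):
        stat, df, p = chi_square_independence(
            np.array([[200, 64, 48], [45, 12, 7]])
        )
        assert round(p, 3) == 0.573

    def test_zero_margin_raises(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_independence(np.array([[0, 0], [1, 2]]))

    def test_table_invariants(self):
        with pytest.raises(ValueError):
            ContingencyTable(np.array([[1, 2]]))


class TestKruskalWallis:
    def test_identical_groups_give_zero(self):
        h, p = kruskal_wallis([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert h == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_rank_example(self):
        h, p = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert h == pytest.approx(27 / 7, abs=1e-9)
        assert p == pytest.approx(0.0495, abs=5e-4)

    def test_constant_data_warns_and_returns_one(self):
        with pytest.warns(RuntimeWarning):
            h, p = kruskal_wallis([[2.0, 2.0], [2.0, 2.0]])
        assert (h, p) == (0.0, 1.0)

    def test_type_one_error_rate_near_nominal(self):
        rng = np.random.default_rng(7)
        rejections = 0
        n_sim = 300
        for _ in range(n_sim):
            groups = [rng.standard_normal(200) for _ in range(3)]
            _, p = kruskal_wallis(groups)
            rejections += p < 0.05
        assert abs(rejections / n_sim - 0.05) < 0.03


class TestBootstrapCompare:
    @staticmethod
    def auc_metric(scores, targets):
        from sklearn.metrics import roc_auc_score

        if len(np.unique(targets)) < 2:
            raise ValueError("single class")
        return roc_auc_score(targets, scores)

    def test_identical_predictions_give_zero_delta_p_one(self, rng):
        scores = rng.random(60)
        targets = rng.integers(0, 2, 60)
        targets[:2] = [0, 1]
        res = bootstrap_compare(self.auc_metric, scores, scores, targets,
                                n_boot=200, seed=1)
        assert res["delta"] == 0.0
        assert res["p_value"] >= 0.99

    def test_perfect_vs_random_is_significant(self):
        rng = np.random.default_rng(3)
        targets = rng.integers(0, 2, 200)
        targets[:2] = [0, 1]
        perfect = targets + 0.01 * rng.random(200)
        random_scores = rng.random(200)
        res = bootstrap_compare(self.auc_metric, perfect, random_scores,
                                targets, n_boot=1000, seed=0)
        assert res["p_value"] < 0.01
        assert res["delta"] > 0.3

    def test_fixed_seed_reproduces_interval(self, rng):
        scores_a = rng.random(50)
        scores_b = rng.random(50)
        targets = rng.integers(0, 2, 50)
        targets[:2] = [0, 1]
        r1 = bootstrap_compare(self.auc_metric, scores_a, scores_b, targets,
                               n_boot=200, seed=9)
        r2 = bootstrap_compare(self.auc_metric, scores_a, scores_b, targets,
                               n_boot=200, seed=9)
        assert (r1["ci_low"], r1["ci_high"]) == (r2["ci_low"], r2["ci_high"])


class TestTrialsSummary:
    def test_constant_values_collapse_interval(self):
        s = trials_summary([0.8] * 10)
        assert s.as_tuple() == (0.8, 0.8, 0.8)

    def test_two_value_half_width(self):
        s = trials_summary([0.7, 0.9])
        assert s.point == pytest.approx(0.8)
        assert s.ci_high - s.point == pytest.approx(
            1.96 * np.std([0.7, 0.9], ddof=1) / np.sqrt(2)
        )

    def test_single_value_raises(self):
        with pytest.raises(ValueError):
            trials_summary([0.5])

    def test_ci_width_shrinks_like_root_n(self):
        rng = np.random.default_rng(0)
        values = rng.normal(0.8, 0.05, 400)
        w_small = trials_summary(values[:25]).ci_high - \
            trials_summary(values[:25]).ci_low
        w_large = trials_summary(values).ci_high - trials_summary(values).ci_low
        assert w_large < w_small / 2  # 16× the sample → ~4× narrower
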