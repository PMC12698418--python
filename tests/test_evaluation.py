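"""AUC/C-index identities, bootstrap engine, DeLong test, DCA, calibration."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from collagensig.evaluation import (bootstrap_ci, c_index, calibration_curve,
                                    classification_metrics, decision_curve,
                                    delong_test, roc_auc, youden_threshold)

from oracles import auc_oracle


class TestAUC:
    def test_known_small_cases(self):
        assert roc_auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0
        assert roc_auc([1, 2, 3, 4], [0, 1, 0, 1]) == 0.75
        assert roc_auc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2], [1, 1])

    @given(st.lists(st.integers(0, 8), min_size=4, max_size=30),
           st.randoms(use_true_random=False))
    def test_matches_pairwise_enumeration(self, scores, rnd):
        labels = [rnd.randint(0, 1) for _ in scores]
        if len(set(labels)) < 2:
            labels[0], labels[1] = 0, 1
        assert roc_auc(scores, labels) == pytest.approx(
            auc_oracle(scores, labels), abs=1e-12)

    @given(st.lists(st.integers(-500, 500), min_size=4, max_size=25,
                    unique=True).map(lambda l: [v / 100 for v in l]))
    def test_invariant_under_monotone_transform(self, scores):
        labels = [i % 2 for i in range(len(scores))]
        base = roc_auc(scores, labels)
        assert roc_auc(np.exp(scores), labels) == pytest.approx(base)
        assert roc_auc(3 * np.asarray(scores) - 7, labels) == pytest.approx(base)

    def test_c_index_is_auc_alias(self):
        rng = np.random.default_rng(0)
        s = rng.random(200)
        y = rng.integers(0, 2, 200)
        assert c_index(s, y) == roc_auc(s, y)

    def test_random_ranking_near_half(self):
        rng = np.random.default_rng(1)
        assert c_index(rng.random(1000),
                       rng.integers(0, 2, 1000)) == pytest.approx(0.5, abs=0.05)


class TestBootstrap:
    def test_constant_metric_zero_width(self):
        lo, hi = bootstrap_ci(lambda s, y: 0.7, np.arange(40.0),
                              np.tile([0, 1], 20), B=100, seed=0)
        assert lo == hi == 0.7

    def test_seed_reproducible(self):
        rng = np.random.default_rng(2)
        s, y = rng.random(100), rng.integers(0, 2, 100)
        assert bootstrap_ci(roc_auc, s, y, B=200, seed=5) == \
            bootstrap_ci(roc_auc, s, y, B=200, seed=5)

    def test_interval_brackets_point_estimate(self):
        rng = np.random.default_rng(3)
        y = np.repeat([0, 1], 100)
        s = np.concatenate([rng.normal(0, 1, 100), rng.normal(1, 1, 100)])
        lo, hi = bootstrap_ci(roc_auc, s, y, B=1000, seed=1)
        assert lo < roc_auc(s, y) < hi

    def test_small_b_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci(roc_auc, [1, 2], [0, 1], B=10)


class TestDeLong:
    def test_identical_scores_give_p_one(self):
        rng = np.random.default_rng(4)
        s = rng.random(60)
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        delta, p = delong_test(s, s, y)
        assert delta == 0.0 and p == 1.0

    def test_antisymmetric_in_argument_order(self):
        rng = np.random.default_rng(5)
        a, b = rng.random(80), rng.random(80)
        y = rng.integers(0, 2, 80)
        y[:2] = [0, 1]
        d_ab, p_ab = delong_test(a, b, y)
        d_ba, p_ba = delong_test(b, a, y)
        assert d_ab == pytest.approx(-d_ba)
        assert p_ab == pytest.approx(p_ba)

    def test_agrees_with_paired_permutation_oracle(self):
        """n=20: two-sided p within 0.02 of a 1e5-replicate permutation
        reference that randomly exchanges the paired scores."""
        rng = np.random.default_rng(6)
        y = np.repeat([0, 1], 10)
        a = y * 0.8 + rng.normal(0, 1, 20)
        b = y * 0.3 + rng.normal(0, 1, 20)
        _, p_delong = delong_test(a, b, y)

        pos, neg = np.flatnonzero(y == 1), np.flatnonzero(y == 0)

        def fast_auc(s):
            return (s[:, pos][:, :, None] > s[:, neg][:, None, :]).mean(axis=(1, 2)) \
                + 0.5 * (s[:, pos][:, :, None] == s[:, neg][:, None, :]).mean(axis=(1, 2))

        B = 100_000
        swap = rng.random((B, 20)) < 0.5
        A = np.where(swap, b, a)
        Bm = np.where(swap, a, b)
        perm_delta = fast_auc(A) - fast_auc(Bm)
        obs = roc_auc(a, y) - roc_auc(b, y)
        p_perm = np.mean(np.abs(perm_delta) >= abs(obs) - 1e-12)
        assert p_delong == pytest.approx(p_perm, abs=0.02)


class TestDecisionCurve:
    def test_treat_none_is_zero_and_treat_all_closed_form(self):
        rng = np.random.default_rng(7)
        y = (rng.random(1000) < 0.41).astype(float)
        p = rng.random(1000)
        dc = decision_curve(p, y, thresholds=[0.1, 0.3])
        assert np.all(dc.net_benefit_none == 0.0)
        prev = y.mean()
        assert dc.net_benefit_all[0] == pytest.approx(prev - (1 - prev) / 9)

    def test_perfect_predictor_plateaus_at_prevalence(self):
        y = np.repeat([0, 1], 50)
        p = np.repeat([0.05, 0.95], 50)
        dc = decision_curve(p, y, thresholds=np.arange(0.1, 0.9, 0.1))
        assert np.allclose(dc.net_benefit_model, y.mean())

    def test_boundary_thresholds_rejected(self):
        y = np.repeat([0, 1], 5)
        with pytest.raises(ValueError, match="strictly"):
            decision_curve(np.linspace(0, 1, 10), y, thresholds=[0.0, 0.5])

    def test_net_benefit_never_exceeds_prevalence(self):
        rng = np.random.default_rng(8)
        y = rng.integers(0, 2, 500).astype(float)
        p = rng.random(500)
        dc = decision_curve(p, y)
        assert np.all(dc.net_benefit_model <= y.mean() + 1e-12)


class TestClassificationMetrics:
    def test_constructed_confusion_arithmetic(self):
        # (TP, FN, FP, TN) = (76, 10, 30, 71) at threshold 0.5
        probs = np.concatenate([np.full(76, 0.9), np.full(10, 0.1),
                                np.full(30, 0.9), np.full(71, 0.1)])
        labels = np.concatenate([np.ones(86), np.zeros(101)])
        point, cis, conf = classification_metrics(probs, labels, 0.5,
                                                  B=100, seed=0)
        assert conf == {"TP": 76, "FN": 10, "FP": 30, "TN": 71}
        assert point["sensitivity"] == pytest.approx(76 / 86)
        assert point["npv"] == pytest.approx(71 / 81)
        assert point["ppv"] == pytest.approx(76 / 106)
        assert point["accuracy"] == pytest.approx(147 / 187)

    def test_perfect_classifier_scores_one_everywhere(self):
        probs = np.concatenate([np.full(20, 0.9), np.full(20, 0.1)])
        labels = np.concatenate([np.ones(20), np.zeros(20)])
        point, _, _ = classification_metrics(probs, labels, 0.5, B=100, seed=0)
        assert all(v == 1.0 for v in point.values())

    def test_youden_threshold_separates_clean_split(self):
        probs = np.concatenate([np.full(30, 0.8), np.full(30, 0.2)])
        labels = np.concatenate([np.ones(30), np.zeros(30)])
        t = youden_threshold(probs, labels)
        assert 0.2 < t <= 0.8


class TestCalibration:
    def test_degenerate_perfect_probs_sit_on_diagonal(self):
        y = np.repeat([0.0, 1.0], 30)
        curve = calibration_curve(y, y, bins=5)
        assert np.allclose(curve.mean_predicted, curve.observed)

    def test_constant_probability_single_point(self):
        rng = np.random.default_rng(9)
        y = (rng.random(400) < 0.3).astype(float)
        curve = calibration_curve(np.full(400, 0.3), y, bins=10)
        assert len(curve) == 1
        assert curve.observed[0] == pytest.approx(0.3, abs=0.05)

    def test_well_specified_model_calibrates_within_decile_tolerance(self):
        rng = np.random.default_rng(10)
        p = 1 / (1 + np.exp(-rng.normal(0, 1.5, 2000)))
        y = (rng.random(2000) < p).astype(float)
        curve = calibration_curve(p, y, bins=10)
        assert np.max(np.abs(curve.mean_predicted - curve.observed)) < 0.1

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            calibration_curve([0.2, 0.8], [0, 1], bins=2)
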