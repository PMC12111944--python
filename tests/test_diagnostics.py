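"""Tests for ROC construction, cut-off selection and statistical routines.

Every ROC quantity is checked against an exhaustive brute-force oracle
on small fixtures, and against scikit-learn as an independent
implementation on random data.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hepindex.diagnostics import (
    compare_auc,
    group_compare,
    optimal_cutoff,
    performance_at,
    roc_curve,
    rule_cutoffs,
    spearman_ci,
    stepwise_logistic,
)


def brute_auc(scores, labels) -> float:
    """Pairwise concordance with ties counted one half."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def brute_confusion(scores, labels, t):
    tp = sum(1 for s, l in zip(scores, labels) if l and s >= t)
    fp = sum(1 for s, l in zip(scores, labels) if not l and s >= t)
    fn = sum(1 for s, l in zip(scores, labels) if l and s < t)
    tn = sum(1 for s, l in zip(scores, labels) if not l and s < t)
    return tp, fp, tn, fn


def brute_best_youden(scores, labels):
    """Exhaustive scan of Se+Sp over all candidate thresholds."""
    n_pos = sum(labels)
    n_neg = len(labels) - n_pos
    cands = sorted(set(scores)) + [max(scores) + 1.0]
    best = None
    for t in cands:
        tp, fp, tn, fn = brute_confusion(scores, labels, t)
        j = tp / n_pos + tn / n_neg
        if best is None or j > best[1] + 1e-12:
            best = (t, j)
    return best


class TestRocCurve:
    def test_four_point_example(self):
        curve = roc_curve([3, 5, 1, 4], [True, True, False, False])
        assert curve.auc == pytest.approx(0.75)

    def test_perfect_separation(self):
        curve = roc_curve([5, 6, 1, 2], [True, True, False, False])
        assert curve.auc == 1.0

    def test_all_ties_give_half(self):
        curve = roc_curve([2.0] * 6, [True, False] * 3)
        assert curve.auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([1, 2, 3], [True, True, True])

    def test_curve_monotone_in_threshold(self, rng):
        scores = rng.normal(size=60)
        labels = rng.random(60) < 0.4
        curve = roc_curve(scores, labels)
        assert (np.diff(curve.se_at) <= 1e-12).all()
        assert (np.diff(curve.sp_at) >= -1e-12).all()

    def test_auc_matches_brute_force_and_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        for trial in range(20):
            n = int(rng.integers(6, 50))
            scores = np.round(rng.normal(size=n), 1)  # induce ties
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            curve = roc_curve(scores, labels)
            assert curve.auc == pytest.approx(brute_auc(scores, labels), abs=1e-12)
            assert curve.auc == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12
            )


class TestOptimalCutoff:
    def test_separable_case(self):
        curve = roc_curve([5, 6, 1, 2], [True, True, False, False])
        t, perf = optimal_cutoff(curve)
        assert perf.se.value == 1.0 and perf.sp.value == 1.0
        assert 2 < t <= 5

    def test_small_example_matches_exhaustive_scan(self):
        scores, labels = [3, 5, 1, 4], [True, True, False, False]
        t, perf = optimal_cutoff(roc_curve(scores, labels))
        bt, bj = brute_best_youden(scores, labels)
        assert perf.se.value + perf.sp.value == pytest.approx(bj)
        assert t == bt  # ties resolved toward the lower threshold

    def test_degenerate_all_equal(self):
        t, perf = optimal_cutoff(roc_curve([2, 2, 2, 2], [True, False, True, False]))
        assert perf.se.value + perf.sp.value == pytest.approx(1.0)

    def test_random_fixtures_match_exhaustive_scan(self, rng):
        for _ in range(25):
            n = int(rng.integers(6, 50))
            scores = np.round(rng.normal(size=n), 1)
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            t, perf = optimal_cutoff(roc_curve(scores, labels))
            _, bj = brute_best_youden(scores, labels)
            assert perf.se.value + perf.sp.value == pytest.approx(bj, abs=1e-12)


class TestRuleCutoffs:
    def test_separable_rules_coincide(self):
        curve = roc_curve([5, 6, 1, 2], [True, True, False, False])
        rules = rule_cutoffs(curve)
        assert rules["rule_in"] == rules["rule_out"]
        tp, fp, tn, fn = brute_confusion(
            [5, 6, 1, 2], [True, True, False, False], rules["rule_in"]
        )
        assert fp == 0 and fn == 0

    def test_infeasible_floors_absent(self):
        # fully interleaved classes: no non-degenerate threshold reaches
        # 99.9% sensitivity or specificity
        curve = roc_curve([1, 2, 1.5, 2.5], [True, True, False, False])
        rules = rule_cutoffs(curve, se_floor=0.999, sp_floor=0.999)
        assert rules["rule_in"] is None and rules["rule_out"] is None

    def test_matches_exhaustive_constrained_scan(self, rng):
        for _ in range(25):
            n = int(rng.integers(8, 50))
            scores = np.round(rng.normal(size=n), 1)
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            curve = roc_curve(scores, labels)
            rules = rule_cutoffs(curve, se_floor=0.8, sp_floor=0.74)
            n_pos, n_neg = labels.sum(), (~labels).sum()
            cands = sorted(set(scores)) + [scores.max() + 1.0]

            feas_out = []
            feas_in = []
            for t in cands:
                tp, fp, tn, fn = brute_confusion(scores, labels, t)
                se, sp = tp / n_pos, tn / n_neg
                if se == 0 or sp == 0:  # degenerate operating points excluded
                    continue
                if se >= 0.8:
                    feas_out.append((t, sp))
                if sp >= 0.74:
                    feas_in.append((t, se))
            if feas_out:
                best_sp = max(sp for _, sp in feas_out)
                tp, fp, tn, fn = brute_confusion(scores, labels, rules["rule_out"])
                assert tn / n_neg == pytest.approx(best_sp, abs=1e-12)
            else:
                assert rules["rule_out"] is None
            if feas_in:
                best_se = max(se for _, se in feas_in)
                tp, fp, tn, fn = brute_confusion(scores, labels, rules["rule_in"])
                assert tp / n_pos == pytest.approx(best_se, abs=1e-12)
            else:
                assert rules["rule_in"] is None


class TestPerformanceAt:
    def test_hand_confusion_matrix(self):
        perf = performance_at([5, 3, 1, 4], [True, True, False, False], 3)
        assert perf.se.value == 1.0
        assert perf.sp.value == 0.5
        assert perf.ppv.value == pytest.approx(2 / 3)
        assert perf.npv.value == 1.0

    def test_threshold_above_all_scores(self):
        perf = performance_at([1, 2, 3], [True, False, True], 10)
        assert perf.se.value == 0.0
        assert perf.sp.value == 1.0
        assert perf.ppv is None  # no positive calls

    def test_threshold_below_all_scores(self):
        perf = performance_at([1, 2, 3], [True, False, True], -10)
        assert perf.se.value == 1.0
        assert perf.sp.value == 0.0
        assert perf.npv is None

    def test_wilson_ci_contains_point_estimate(self, rng):
        scores = rng.normal(size=40)
        labels = rng.random(40) < 0.5
        perf = performance_at(scores, labels, 0.0)
        for prop in (perf.se, perf.sp, perf.ppv, perf.npv, perf.accuracy):
            if prop is not None:
                assert prop.ci_low <= prop.value <= prop.ci_high

    def test_invariance_under_joint_monotone_transform(self, rng):
        scores = rng.normal(size=50)
        labels = rng.random(50) < 0.5
        t = 0.3
        a = performance_at(scores, labels, t)
        b = performance_at(np.exp(scores), labels, np.exp(t))
        assert (a.tp, a.fp, a.tn, a.fn) == (b.tp, b.fp, b.tn, b.fn)


class TestCompareAuc:
    def test_identical_scores(self):
        r = compare_auc([1, 2, 3, 4], [1, 2, 3, 4], [True, True, False, False])
        assert r["delta"] == 0.0
        assert r["p_value"] == 1.0

    def test_delta_equals_auc_difference(self, rng):
        scores_a = rng.normal(size=30)
        scores_b = scores_a.copy()
        scores_b[3], scores_b[7] = scores_b[7], scores_b[3]
        labels = rng.random(30) < 0.5
        r = compare_auc(scores_a, scores_b, labels)
        assert r["delta"] == pytest.approx(
            brute_auc(scores_a, labels) - brute_auc(scores_b, labels), abs=1e-12
        )

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(ValueError):
            compare_auc([1, 2, 3], [1, 2], [True, False, True])


class TestSpearmanCI:
    def test_identity(self):
        r = spearman_ci([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert r["rho"] == 1.0

    def test_antitone(self):
        r = spearman_ci([1, 2, 3, 4], [4, 3, 2, 1])
        assert r["rho"] == -1.0

    def test_hand_rank_example(self):
        # appending a tied pair keeps n >= 4 while preserving the ranks
        r = spearman_ci([1, 2, 3, 4], [3, 1, 2, 4])
        d2 = sum((a - b) ** 2 for a, b in zip([1, 2, 3, 4], [3, 1, 2, 4]))
        expected = 1 - 6 * d2 / (4 * 15)
        assert r["rho"] == pytest.approx(expected)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman_ci([1, 1, 1, 1], [1, 2, 3, 4])

    def test_invariant_to_monotone_transform(self, rng):
        x = rng.normal(size=50)
        y = x + rng.normal(size=50)
        a = spearman_ci(x, y)
        b = spearman_ci(np.exp(x), y**3)
        assert a["rho"] == pytest.approx(b["rho"], abs=1e-12)

    def test_ci_brackets_estimate(self, rng):
        x = rng.normal(size=60)
        y = 0.5 * x + rng.normal(size=60)
        r = spearman_ci(x, y)
        assert r["ci_low"] < r["rho"] < r["ci_high"]


class TestGroupCompare:
    def test_identical_categorical_groups(self):
        values = [True, False] * 10
        groups = ["a"] * 10 + ["b"] * 10
        # identical 50/50 composition in both groups
        values = [True, False] * 5 + [True, False] * 5
        r = group_compare(values, groups)
        assert r["test_used"] == "chi2"
        assert r["p"] == pytest.approx(1.0)

    def test_normal_data_routed_to_t(self, rng):
        a = rng.normal(0, 1, 200)
        b = rng.normal(1, 1, 200)
        r = group_compare(
            np.concatenate([a, b]), ["a"] * 200 + ["b"] * 200
        )
        assert r["test_used"] == "t"
        assert r["p"] < 0.001

    def test_heavy_tails_routed_to_mannwhitney(self, rng):
        a = rng.standard_cauchy(200)
        b = rng.standard_cauchy(200) + 1
        r = group_compare(
            np.concatenate([a, b]), ["a"] * 200 + ["b"] * 200
        )
        assert r["test_used"] == "mannwhitney"

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            group_compare([1.0, 2.0, 3.0], ["a", "a", "a"])

    def test_shifted_normals_power(self, rng):
        """Two normal samples one SD apart are essentially always detected."""
        rejections = 0
        for _ in range(50):
            a = rng.normal(0, 1, 500)
            b = rng.normal(1, 1, 500)
            r = group_compare(np.concatenate([a, b]), ["a"] * 500 + ["b"] * 500)
            rejections += r["p"] < 0.05
        assert rejections == 50


class TestStepwiseLogistic:
    def test_or_identity_for_null_coefficient(self):
        assert np.exp(0.0) == 1.0  # documented contract: OR(beta=0) = 1

    def test_strong_predictor_retained_noise_removed(self, rng):
        n = 2000
        x = pd.DataFrame(
            {
                "signal": rng.normal(size=n),
                "noise1": rng.normal(size=n),
                "noise2": rng.normal(size=n),
            }
        )
        logit = -0.3 + 1.5 * x["signal"]
        y = rng.random(n) < 1 / (1 + np.exp(-logit))
        res = stepwise_logistic(y, x)
        assert "signal" in res.selected
        assert res.odds_ratios["signal"] == pytest.approx(np.exp(1.5), rel=0.2)
        lo, hi = res.or_ci["signal"]
        assert lo < res.odds_ratios["signal"] < hi

    def test_null_outcome_tends_to_empty_model(self, rng):
        empties = 0
        for _ in range(20):
            n = 600
            x = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
            y = rng.random(n) < 0.4
            res = stepwise_logistic(y, x)
            empties += len(res.selected) == 0
        assert empties >= 10  # majority of null replicates

    def test_constant_predictor_rejected(self, rng):
        x = pd.DataFrame({"a": np.ones(100), "b": rng.normal(size=100)})
        y = rng.random(100) < 0.5
        with pytest.raises(ValueError, match="constant"):
            stepwise_logistic(y, x)

    def test_separation_flagged(self):
        x = pd.DataFrame({"a": np.r_[np.zeros(30), np.ones(30)]})
        y = np.r_[np.zeros(30), np.ones(30)].astype(bool)
        res = stepwise_logistic(y, x)
        assert res.separation_flag
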