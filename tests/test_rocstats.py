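"""ROC/AUC machinery against brute-force and library oracles."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from organotrace.frames import DomainError
from organotrace.rocstats import (
    DegenerateLabelsError,
    auc,
    auc_ci,
    bootstrap_auc_ci,
    roc_curve,
    summarize,
    youden_point,
)


def mann_whitney_auc(scores, labels):
    """Brute-force oracle: (wins + 0.5 * ties) over all pos-neg pairs."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (pos.size * neg.size)


class TestRocCurve:
    def test_perfect_separation(self):
        scores = [0.9, 0.8, 0.1, 0.2]
        labels = [True, True, False, False]
        curve = roc_curve(scores, labels)
        assert auc(curve) == 1.0
        # the curve passes through (fpr=0, tpr=1)
        assert any(f == 0.0 and t == 1.0 for f, t in zip(curve.fpr, curve.tpr))
        assert curve.fpr[0] == 0.0 and curve.tpr[0] == 0.0
        assert curve.fpr[-1] == 1.0 and curve.tpr[-1] == 1.0

    def test_complete_ties(self):
        curve = roc_curve([1.0, 1.0, 1.0], [True, False, True])
        assert curve.fpr.tolist() == [0.0, 1.0]
        assert curve.tpr.tolist() == [0.0, 1.0]
        assert auc(curve) == 0.5

    def test_interleaved_toy_case(self):
        # positives {3, 1}, negatives {2}: one win, one loss
        curve = roc_curve([3.0, 1.0, 2.0], [True, True, False])
        assert auc(curve) == 0.5

    def test_monotone_curve(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=30)
        labels = rng.uniform(size=30) < 0.5
        labels[:2] = [True, False]
        curve = roc_curve(scores, labels)
        assert np.all(np.diff(curve.fpr) >= 0)
        assert np.all(np.diff(curve.tpr) >= 0)

    def test_single_class_raises(self):
        with pytest.raises(DegenerateLabelsError):
            roc_curve([1.0, 2.0], [True, True])

    def test_non_finite_scores_rejected(self):
        with pytest.raises(DomainError):
            roc_curve([1.0, np.nan], [True, False])


class TestAUC:
    def test_trapezoid_equals_mann_whitney_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(2, 13))
            scores = rng.integers(0, 6, size=n).astype(float)  # many ties
            labels = rng.uniform(size=n) < 0.5
            if labels.all() or not labels.any():
                labels[0] = ~labels[0]
            got = auc(roc_curve(scores, labels))
            assert abs(got - mann_whitney_auc(scores, labels)) <= 1e-12

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        for _ in range(25):
            scores = rng.normal(size=40)
            labels = rng.uniform(size=40) < 0.4
            if labels.all() or not labels.any():
                labels[0] = ~labels[0]
            assert auc(roc_curve(scores, labels)) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_sign_flip_complement_for_tie_free_scores(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.permutation(np.arange(12, dtype=float))  # tie-free
        labels = rng.uniform(size=12) < 0.5
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        a = auc(roc_curve(scores, labels))
        b = auc(roc_curve(-scores, labels))
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=25)
        labels = rng.uniform(size=25) < 0.5
        labels[:2] = [True, False]
        a = auc(roc_curve(scores, labels))
        b = auc(roc_curve(np.exp(scores), labels))
        assert a == pytest.approx(b, abs=1e-12)

    def test_label_permutation_null_centres_on_half(self):
        rng = np.random.default_rng(7)
        scores = rng.normal(size=24)
        labels = np.array([True] * 12 + [False] * 12)
        aucs = []
        for _ in range(1000):
            aucs.append(auc(roc_curve(scores, rng.permutation(labels))))
        assert abs(np.mean(aucs) - 0.5) <= 0.02


class TestConfidenceIntervals:
    def test_perfect_separation_truncates_to_one(self):
        scores = [3.0, 2.5, 1.0, 0.5]
        labels = [True, True, False, False]
        lo, hi = auc_ci(scores, labels)
        assert hi == 1.0
        assert summarize(scores, labels).degenerate

    def test_delong_close_to_bootstrap(self):
        rng = np.random.default_rng(5)
        scores = np.r_[rng.normal(1.0, 1.0, 50), rng.normal(0.0, 1.0, 50)]
        labels = np.r_[np.ones(50), np.zeros(50)].astype(bool)
        d_lo, d_hi = auc_ci(scores, labels)
        b_lo, b_hi = bootstrap_auc_ci(scores, labels, n_boot=2000, seed=1)
        assert abs(d_lo - b_lo) <= 0.02
        assert abs(d_hi - b_hi) <= 0.02

    def test_interval_contains_point_estimate(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            scores = rng.normal(size=30)
            labels = rng.uniform(size=30) < 0.5
            if labels.all() or not labels.any():
                labels[0] = ~labels[0]
            lo, hi = auc_ci(scores, labels)
            point = auc(roc_curve(scores, labels))
            assert lo - 1e-12 <= point <= hi + 1e-12

    def test_invalid_level_rejected(self):
        with pytest.raises(DomainError):
            auc_ci([1.0, 0.0], [True, False], level=1.5)


class TestYoudenPoint:
    def test_perfect_separation_hits_both_corners(self):
        curve = roc_curve([0.9, 0.8, 0.1, 0.2], [True, True, False, False])
        _, sens, spec = youden_point(curve)
        assert sens == 1.0 and spec == 1.0

    def test_toy_case_threshold_scan(self):
        # positives {3, 1}, negatives {2}: J maximized by thresholding at 3
        curve = roc_curve([3.0, 1.0, 2.0], [True, True, False])
        threshold, sens, spec = youden_point(curve)
        assert sens == 0.5 and spec == 1.0
        assert threshold == 3.0

    def test_complete_ties_degenerate_corner(self):
        # documented tie rule: all-tied scores land on the all-positive corner
        curve = roc_curve([1.0, 1.0], [True, False])
        threshold, sens, spec = youden_point(curve)
        assert (sens, spec) == (1.0, 0.0)
        assert threshold == 1.0

    def test_summary_is_internally_consistent(self):
        rng = np.random.default_rng(9)
        scores = np.r_[rng.normal(1.5, 1.0, 20), rng.normal(0.0, 1.0, 20)]
        labels = np.r_[np.ones(20), np.zeros(20)].astype(bool)
        summary = summarize(scores, labels)
        assert summary.ci_low <= summary.auc <= summary.ci_high
        assert 0 <= summary.sensitivity <= 1 and 0 <= summary.specificity <= 1
        assert summary.n_positive == 20 and summary.n_negative == 20
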