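"""ROC/AUC, operating point, CF classification and the upper-bound estimator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from idrfold import (
    best_operating_point,
    classify_idrs,
    extract_idr_segments,
    mann_whitney_u,
    pearson_correlation,
    roc_curve,
    upper_bound_fraction,
)


def _pairwise_auc(scores, labels):
    """Brute-force probability that a random positive outranks a random
    negative, ties counting one half."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestROC:
    def test_toy_auc(self):
        roc = roc_curve([90, 80, 60, 40], [True, False, True, False])
        assert roc.auc == pytest.approx(0.75, abs=1e-12)

    def test_perfect_separation(self):
        roc = roc_curve([9, 8, 7, 2, 1], [True, True, True, False, False])
        assert roc.auc == pytest.approx(1.0, abs=1e-12)

    def test_curve_endpoints_and_monotonicity(self, rng):
        scores = rng.normal(size=500)
        labels = rng.random(500) < 0.4
        roc = roc_curve(scores, labels)
        assert roc.tpr[0] == roc.fpr[0] == 0.0
        assert roc.tpr[-1] == roc.fpr[-1] == 1.0
        assert np.all(np.diff(roc.tpr) >= 0) and np.all(np.diff(roc.fpr) >= 0)

    def test_random_labels_auc_near_half(self, rng):
        scores = rng.normal(size=10_000)
        labels = rng.random(10_000) < 0.5
        assert roc_curve(scores, labels).auc == pytest.approx(0.5, abs=0.02)

    def test_matches_pairwise_count_with_ties(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 60))
            scores = rng.integers(0, 10, n).astype(float)  # many ties
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            assert roc_curve(scores, labels).auc == pytest.approx(
                _pairwise_auc(scores, labels), abs=1e-12
            )

    def test_auc_equals_mann_whitney_u(self, rng):
        scores = rng.integers(0, 50, 300).astype(float)
        labels = rng.random(300) < 0.3
        pos, neg = scores[labels], scores[~labels]
        u = mann_whitney_u(pos, neg, mode="normal").u
        auc = roc_curve(scores, labels).auc
        assert auc == pytest.approx(u / (len(pos) * len(neg)), abs=1e-12)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None)
    def test_auc_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=200)
        labels = rng.random(200) < 0.5
        if labels.all() or not labels.any():
            return
        base = roc_curve(scores, labels).auc
        transformed = roc_curve(np.exp(scores * 0.5) + 3, labels).auc
        assert transformed == pytest.approx(base, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([1.0, 2.0], [True, True])

    def test_gaussian_closed_form(self):
        # empirical AUC of two Gaussian score classes converges to
        # Phi(dmu / sqrt(s1^2 + s2^2))
        from scipy.stats import norm

        rng = np.random.default_rng(99)
        pos = rng.normal(75, 10, 20_000)
        neg = rng.normal(55, 15, 20_000)
        scores = np.concatenate([pos, neg])
        labels = np.repeat([True, False], 20_000)
        expected = norm.cdf(20 / np.sqrt(10**2 + 15**2))
        assert roc_curve(scores, labels).auc == pytest.approx(expected, abs=0.01)


class TestOperatingPoint:
    def test_toy_ratio_maximum(self):
        roc = roc_curve([90, 80, 60, 40], [True, False, True, False])
        op = best_operating_point(roc)
        assert op.threshold == 60
        assert op.tpr == pytest.approx(1.0)
        assert op.fpr == pytest.approx(0.5)
        assert op.ratio == pytest.approx(2.0)

    def test_degenerate_perfect_classifier(self):
        roc = roc_curve([9, 8, 2, 1], [True, True, False, False])
        op = best_operating_point(roc)
        assert op.degenerate and op.fpr == 0.0 and op.tpr == 1.0
        assert op.threshold == 8

    def test_appended_low_negative_leaves_choice_unchanged(self):
        scores = [90.0, 80.0, 60.0, 40.0]
        labels = [True, False, True, False]
        base = best_operating_point(roc_curve(scores, labels))
        extended = best_operating_point(
            roc_curve(scores + [10.0], labels + [False])
        )
        assert extended.threshold == base.threshold


class TestClassifyIdrs:
    def test_confident_segment_is_cf(self, rng):
        from idrfold import ResidueTrack

        track = ResidueTrack("X", "", np.full(30, 91.0), np.full(30, 0.9))
        segs = extract_idr_segments(track)
        calls = classify_idrs(segs, [track])
        assert all(calls.values())

    def test_low_confidence_segment_is_not_cf(self):
        from idrfold import ResidueTrack

        track = ResidueTrack("X", "", np.full(30, 69.0), np.full(30, 0.9))
        segs = extract_idr_segments(track)
        assert not any(classify_idrs(segs, [track]).values())

    def test_recovery_at_default_separation(self, small_proteome, track_map):
        _, tracks, truth = small_proteome
        segs = []
        for t in tracks:
            segs.extend(extract_idr_segments(t))
        calls = classify_idrs(segs, track_map)
        tp = fp = fn = tn = 0
        for seg, call in calls.items():
            is_cf = bool(truth.cf[seg.protein_id][seg.start - 1])
            tp += call and is_cf
            fp += call and not is_cf
            fn += (not call) and is_cf
            tn += (not call) and not is_cf
        assert tp / (tp + fn) >= 0.9  # sensitivity
        assert tn / (tn + fp) >= 0.9  # specificity


class TestUpperBound:
    def test_reference_values(self):
        assert upper_bound_fraction(0.15, 0.60) == pytest.approx(0.25, abs=1e-12)

    def test_perfect_sensitivity_identity(self):
        assert upper_bound_fraction(0.37, 1.0) == 0.37

    def test_cap_with_warning(self):
        with pytest.warns(UserWarning, match="capping"):
            assert upper_bound_fraction(0.9, 0.6) == 1.0

    def test_zero_sensitivity_rejected(self):
        with pytest.raises(ValueError):
            upper_bound_fraction(0.5, 0.0)


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pearson_correlation(x, 2 * x + 1).r == pytest.approx(1.0)
        assert pearson_correlation(x, -x).r == pytest.approx(-1.0)

    def test_hand_arithmetic(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 3.0, 2.0, 5.0])
        # direct formula from sums: r = (n*Sxy - Sx*Sy) / sqrt((n*Sxx-Sx^2)(n*Syy-Sy^2))
        n = 4
        r_hand = (n * (x * y).sum() - x.sum() * y.sum()) / np.sqrt(
            (n * (x * x).sum() - x.sum() ** 2) * (n * (y * y).sum() - y.sum() ** 2)
        )
        result = pearson_correlation(x, y)
        assert result.r == pytest.approx(r_hand, abs=1e-12)
        assert result.r_squared == pytest.approx(r_hand**2, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
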