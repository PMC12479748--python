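"""Confusion-matrix metrics, AUC estimators, splits and cross-validation."""

import statistics

import numpy as np
import pytest

from ecgfusion.evaluation import (ConfusionCounts, confusion, kfold_cv,
                                  metrics_from_confusion, roc_auc,
                                  stratified_split)


def pair_counting_auc(scores, labels):
    """Independent concordance estimator: P(score_pos > score_neg) with
    ties counted half, enumerated over all positive-negative pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos, neg = scores[labels], scores[~labels]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (pos.size * neg.size)


class TestConfusion:
    def test_perfect_predictions(self):
        y = np.r_[np.ones(10), np.zeros(10)]
        c = confusion(y, y, positive_class=1)
        assert (c.tp, c.tn, c.fp, c.fn) == (10, 10, 0, 0)

    def test_all_positive_predictor(self):
        y = np.r_[np.ones(10), np.zeros(10)]
        c = confusion(y, np.ones(20), positive_class=1)
        assert (c.tp, c.fp, c.tn, c.fn) == (10, 10, 0, 0)

    def test_counts_sum_to_n(self, rng):
        y = rng.integers(0, 2, 37)
        p = rng.integers(0, 2, 37)
        assert confusion(y, p, 1).total == 37

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion([0, 1], [1], 1)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fp=0, tn=0, fn=0)


class TestMetrics:
    def test_reported_two_class_counts(self):
        """129 positives with 128 detected; 128 negatives with 124
        detected: sensitivity 99.2, specificity 97 (integer), accuracy
        98.05, F1 98.1 at the respective printed precisions."""
        rep = metrics_from_confusion(ConfusionCounts(tp=128, fn=1, tn=124, fp=4))
        assert round(rep.sensitivity, 1) == 99.2
        assert round(rep.specificity) == 97
        assert round(rep.accuracy, 2) == 98.05
        assert round(rep.f1, 1) == 98.1

    def test_scale_free(self):
        a = metrics_from_confusion(ConfusionCounts(12, 3, 20, 5))
        b = metrics_from_confusion(ConfusionCounts(84, 21, 140, 35))
        for k in ("sensitivity", "specificity", "accuracy", "f1"):
            np.testing.assert_allclose(getattr(a, k), getattr(b, k))

    def test_positive_class_flip_swaps_sens_spec(self):
        c = ConfusionCounts(tp=30, fp=5, tn=50, fn=10)
        flipped = ConfusionCounts(tp=c.tn, fp=c.fn, tn=c.tp, fn=c.fp)
        a, b = metrics_from_confusion(c), metrics_from_confusion(flipped)
        np.testing.assert_allclose(a.sensitivity, b.specificity)
        np.testing.assert_allclose(a.specificity, b.sensitivity)

    def test_zero_denominator_flagged(self):
        with pytest.warns(UserWarning, match="sensitivity"):
            rep = metrics_from_confusion(ConfusionCounts(0, 2, 5, 0))
        assert np.isnan(rep.sensitivity)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_uninformative_scores(self):
        assert roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_enumerated_example(self):
        assert roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])

    def test_trapezoid_equals_pair_counting(self, rng):
        """On random instances (n <= 50, heavy ties) the trapezoidal AUC
        equals the brute-force concordance estimator exactly."""
        from sklearn.metrics import roc_auc_score

        for trial in range(30):
            n = int(rng.integers(4, 51))
            scores = rng.integers(0, 6, n) / 5.0   # many ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            got = roc_auc(scores, labels)
            np.testing.assert_allclose(got, pair_counting_auc(scores, labels),
                                       atol=1e-12)
            np.testing.assert_allclose(got, roc_auc_score(labels, scores),
                                       atol=1e-12)


class TestStratifiedSplit:
    def test_balanced_sizes(self):
        y = np.r_[np.zeros(100), np.ones(100)]
        tr, te = stratified_split(y, 0.2, seed=0)
        assert te.size == 40 and tr.size == 160
        assert (y[te] == 0).sum() == 20 and (y[te] == 1).sum() == 20

    def test_partition(self, rng):
        y = rng.integers(0, 2, 83)
        tr, te = stratified_split(y, 0.25, seed=3)
        assert np.intersect1d(tr, te).size == 0
        assert np.union1d(tr, te).size == 83

    def test_seed_reproducibility(self):
        y = np.r_[np.zeros(30), np.ones(30)]
        assert np.array_equal(stratified_split(y, 0.2, 5)[1],
                              stratified_split(y, 0.2, 5)[1])
        assert not np.array_equal(stratified_split(y, 0.2, 5)[1],
                                  stratified_split(y, 0.2, 6)[1])

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_split(np.array([0, 0, 0, 1]), 0.2, 0)


class TestKFold:
    def test_fold_balance_and_assignment(self):
        y = np.r_[np.zeros(23), np.ones(27)]
        rec = kfold_cv(y, lambda tr, te: (y[te], y[te].astype(float)),
                       k=5, seed=0)
        assert rec.fold_assignment.min() == 0
        for cls in (0, 1):
            sizes = [((rec.fold_assignment == f) & (y == cls)).sum()
                     for f in range(5)]
            assert max(sizes) - min(sizes) <= 1

    def test_constant_classifier_accuracy_is_majority_fraction(self):
        y = np.r_[np.zeros(15), np.ones(35)]
        rep = kfold_cv(y, lambda tr, te: (np.ones(te.size),
                                          np.full(te.size, 0.5)),
                       k=5, seed=1)
        for f, r in enumerate(rep.fold_reports):
            frac = y[rep.fold_assignment == f].mean()
            np.testing.assert_allclose(r.accuracy, 100 * frac)

    def test_mean_sd_match_independent_recompute(self):
        y = np.r_[np.zeros(20), np.ones(20)]
        rng = np.random.default_rng(2)
        rep = kfold_cv(y, lambda tr, te: ((rng.uniform(size=te.size) > 0.3)
                                          .astype(int),
                                          rng.uniform(size=te.size)),
                       k=4, seed=2)
        accs = [r.accuracy for r in rep.fold_reports]
        np.testing.assert_allclose(rep.mean["accuracy"],
                                   statistics.fmean(accs), atol=1e-12)
        np.testing.assert_allclose(rep.sd["accuracy"],
                                   statistics.stdev(accs), atol=1e-12)

    def test_class_smaller_than_k_rejected(self):
        with pytest.raises(ValueError):
            kfold_cv(np.array([0, 0, 0, 1, 1, 1, 1, 1]),
                     lambda tr, te: (np.zeros(te.size), np.zeros(te.size)),
                     k=5, seed=0)
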