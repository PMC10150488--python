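"""Negative sampling, soft voting, metric forms and the CV protocol."""

import numpy as np
import pytest
from sklearn.metrics import average_precision_score, roc_auc_score

from mirvote import (
    AssociationTable,
    EnsembleSpec,
    classification_metrics,
    pr_auc,
    roc_auc,
    run_cross_validation,
    sample_negatives,
    soft_vote,
    train_ensemble,
)
from mirvote.features import FeatureTable
from mirvote.learn import TrainingSet, roc_curve_points


def _assoc(A):
    A = np.asarray(A, dtype=np.int8)
    pairs = [
        (f"m{i}", f"d{j}")
        for i in range(A.shape[0])
        for j in range(A.shape[1])
        if A[i, j]
    ]
    return AssociationTable.from_pairs(pairs) if pairs else None


def _training_set(X, y, seed=0):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    table = FeatureTable(
        pairs=[(i, 0) for i in range(len(y))],
        values=X,
        labels=y,
        block_bounds=((0, X.shape[1]), (X.shape[1], X.shape[1]), (X.shape[1], X.shape[1])),
    )
    return TrainingSet(table, y, [], [], seed)


def _separable(n=40, dim=4, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, dim))
    y = (X[:, 0] > 0).astype(int)
    X[:, 0] += np.where(y == 1, 3.0, -3.0)
    return X, y


class TestSampleNegatives:
    @pytest.fixture()
    def assoc2x2(self):
        assoc = AssociationTable.from_pairs([("m0", "d0"), ("m1", "d1")])
        assoc.A[1, 1] = 0  # one positive, three unknown pairs
        return assoc

    def test_count_zero(self, assoc2x2):
        assert sample_negatives(assoc2x2, 0, seed=1) == []

    def test_exhaustive_small_case(self, assoc2x2):
        neg = sample_negatives(assoc2x2, 3, seed=1)
        assert sorted(neg) == [(0, 1), (1, 0), (1, 1)]

    def test_seed_reproducibility(self, default_fixture):
        assoc = default_fixture.associations
        a = sample_negatives(assoc, 100, seed=5)
        b = sample_negatives(assoc, 100, seed=5)
        c = sample_negatives(assoc, 100, seed=6)
        assert a == b
        assert a != c

    def test_negatives_disjoint_from_positives(self, default_fixture):
        assoc = default_fixture.associations
        neg = set(sample_negatives(assoc, 200, seed=3))
        assert neg.isdisjoint(set(assoc.positive_pairs()))

    def test_count_too_large(self, assoc2x2):
        with pytest.raises(ValueError, match="unknown pairs"):
            sample_negatives(assoc2x2, 4, seed=1)

    def test_exclude_disease_column(self, default_fixture):
        assoc = default_fixture.associations
        neg = sample_negatives(assoc, 150, seed=2, exclude_disease=3)
        assert all(j != 3 for _, j in neg)


class TestSoftVote:
    def test_mean_of_members(self):
        probs = np.array([[0.2], [0.4], [0.6], [0.8]])
        assert soft_vote(probs)[0] == pytest.approx(0.5)

    def test_identity_on_agreement(self):
        probs = np.full((4, 5), 0.73)
        assert np.allclose(soft_vote(probs), 0.73)

    def test_bounded_by_member_envelope(self, rng):
        probs = rng.random((4, 50))
        vote = soft_vote(probs)
        assert np.all(vote >= probs.min(axis=0)) and np.all(vote <= probs.max(axis=0))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            soft_vote(np.array([[1.2], [0.5]]))


class TestClassificationMetrics:
    def test_direct_substitution(self):
        # TP=3, FP=1, FN=1 on 5 scored samples
        y = [1, 1, 1, 0, 1]
        s = [0.9, 0.8, 0.7, 0.6, 0.1]
        prf = classification_metrics(y, s, threshold=0.5)
        assert (prf.precision, prf.recall, prf.f1) == (0.75, 0.75, 0.75)
        assert not prf.undefined

    def test_perfect_scores(self):
        prf = classification_metrics([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1])
        assert (prf.precision, prf.recall, prf.f1) == (1.0, 1.0, 1.0)

    def test_no_predicted_positives_flagged(self):
        prf = classification_metrics([1, 0], [0.2, 0.1], threshold=0.5)
        assert prf.precision == 0.0 and prf.recall == 0.0
        assert "precision" in prf.undefined


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]) == 1.0

    def test_all_ties_half(self):
        assert roc_auc([1, 0, 1, 0], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_hand_counted_example(self):
        # 3 concordant of 4 positive-negative pairs
        assert roc_auc([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.1]) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([1, 1], [0.5, 0.6])

    def test_concordance_equals_trapezoid_and_reference(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 200))
            y = rng.integers(0, 2, size=n)
            if y.sum() in (0, n):
                y[0], y[1] = 0, 1
            s = np.round(rng.random(n), 2)  # coarse grid forces ties
            auc = roc_auc(y, s)
            pts = roc_curve_points(y, s)
            trap = np.trapezoid(pts[:, 1], pts[:, 0])
            assert auc == pytest.approx(trap, abs=1e-12)
            assert auc == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        y = rng.integers(0, 2, size=100)
        y[:2] = [0, 1]
        s = rng.random(100)
        assert roc_auc(y, s) == pytest.approx(roc_auc(y, np.exp(3 * s)), abs=1e-12)


def _brute_pr_auc(y, s):
    """Threshold-sweep oracle: accumulate precision * recall increments."""
    y = np.asarray(y)
    s = np.asarray(s)
    area, prev_recall = 0.0, 0.0
    for t in sorted(set(s), reverse=True):
        pred = s >= t
        tp = int(np.sum(pred & (y == 1)))
        recall = tp / y.sum()
        precision = tp / pred.sum()
        area += precision * (recall - prev_recall)
        prev_recall = recall
    return area


class TestPrAuc:
    def test_perfect_separation(self):
        assert pr_auc([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]) == 1.0

    def test_single_positive_ranked_first(self):
        assert pr_auc([1, 0, 0, 0], [0.9, 0.5, 0.4, 0.1]) == 1.0

    def test_matches_threshold_sweep_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 120))
            y = rng.integers(0, 2, size=n)
            if y.sum() == 0:
                y[0] = 1
            s = np.round(rng.random(n), 2)
            assert pr_auc(y, s) == pytest.approx(_brute_pr_auc(y, s), abs=1e-12)
            assert pr_auc(y, s) == pytest.approx(
                average_precision_score(y, s), abs=1e-12
            )

    def test_no_positive_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            pr_auc([0, 0], [0.5, 0.4])


class TestTrainEnsemble:
    def test_separable_training_accuracy(self):
        X, y = _separable()
        model = train_ensemble(_training_set(X, y))
        pred = (model.predict_proba(X) >= 0.5).astype(int)
        assert np.array_equal(pred, y)

    def test_single_member_degenerates_to_member(self):
        X, y = _separable(seed=1)
        spec = EnsembleSpec(members=("rf",))
        model = train_ensemble(_training_set(X, y), spec)
        assert np.array_equal(
            model.predict_proba(X), model.member_probabilities(X)[0]
        )

    def test_refit_is_deterministic(self):
        X, y = _separable(n=60, seed=2)
        p1 = train_ensemble(_training_set(X, y, seed=4)).predict_proba(X)
        p2 = train_ensemble(_training_set(X, y, seed=4)).predict_proba(X)
        assert np.array_equal(p1, p2)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        with pytest.raises(ValueError, match="single class"):
            train_ensemble(_training_set(X, np.ones(10, dtype=int)))

    def test_width_mismatch_rejected(self):
        X, y = _separable()
        model = train_ensemble(_training_set(X, y))
        with pytest.raises(ValueError, match="width"):
            model.predict_proba(X[:, :2])

    def test_unknown_member_rejected(self):
        with pytest.raises(ValueError, match="unknown ensemble members"):
            EnsembleSpec(members=("svm", "catboost"))


class TestCrossValidation:
    def test_separable_aucs_unity(self):
        X, y = _separable(n=80, seed=3)
        report = run_cross_validation(
            _training_set(X, y), EnsembleSpec(members=("rf",)), folds=5, seed=0
        )
        assert report.mean("auc") == 1.0
        assert all(f.auc == 1.0 for f in report.folds)

    def test_fold_sizes_and_stratification(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(103, 3))
        y = np.r_[np.ones(51, dtype=int), np.zeros(52, dtype=int)]
        from sklearn.model_selection import StratifiedKFold

        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        global_frac = y.mean()
        for _, te in skf.split(X, y):
            assert len(te) in (20, 21)
            # positive count within +-1 of the proportional share
            assert abs(y[te].sum() - global_frac * len(te)) <= 1.0

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(500, 5))
        y = rng.integers(0, 2, size=500)
        report = run_cross_validation(
            _training_set(X, y), EnsembleSpec(members=("rf",)), folds=5, repeats=4, seed=0
        )
        assert abs(report.mean("auc") - 0.5) < 0.1

    def test_repeats_extend_folds(self):
        X, y = _separable(n=60, seed=5)
        report = run_cross_validation(
            _training_set(X, y), EnsembleSpec(members=("gbdt",)), folds=3, repeats=2, seed=1
        )
        assert len(report.folds) == 6
        assert report.summary()["average"]["auc"] == pytest.approx(report.mean("auc"))

    def test_bad_fold_counts_rejected(self):
        X, y = _separable(n=20)
        with pytest.raises(ValueError, match="folds"):
            run_cross_validation(_training_set(X, y), folds=1)
        y_rare = np.zeros(20, dtype=int)
        y_rare[:3] = 1
        with pytest.raises(ValueError, match="class"):
            run_cross_validation(_training_set(X, y_rare), folds=5)
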