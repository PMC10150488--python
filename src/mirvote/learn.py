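"""Training-set construction, the four-member soft-voting ensemble, and the
cross-validation protocol with precision/recall/F1/AUC/AUPR.

Positives are the known associations; negatives are drawn uniformly without
replacement from the unknown pairs (the zeros of A), by default one per
positive so the training set is balanced.  Four base learners — an RBF-kernel
SVM with calibrated probabilities, gradient-boosted trees, a random forest,
and XGBoost — are fitted on identical rows and combined by soft voting: the
ensemble score of a sample is the unweighted mean of the members'
positive-class probabilities.

Evaluation follows the standard link-prediction protocol: stratified K-fold
cross-validation (default 5 folds), reporting per-fold precision, recall and
F1 at a 0.5 threshold on the voted probability, ROC AUC in its Mann-Whitney
concordance form, and the area under the precision-recall step curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .containers import AssociationTable, SimilarityMatrix
from .features import FeatureTable, PcaModel, assemble_feature_table

MEMBER_NAMES = ("svm", "gbdt", "rf", "xgboost")

DEFAULT_HYPERPARAMS: dict[str, dict] = {
    "svm": {"C": 1.0, "kernel": "rbf", "gamma": "scale"},
    "gbdt": {"n_estimators": 100, "learning_rate": 0.1},
    "rf": {"n_estimators": 100},
    "xgboost": {"n_estimators": 100, "learning_rate": 0.1, "max_depth": 6},
}


@dataclass(frozen=True)
class EnsembleSpec:
    """Which base learners to use and their hyperparameters (soft vote)."""

    members: tuple[str, ...] = MEMBER_NAMES
    hyperparams: Mapping[str, Mapping] = field(default_factory=lambda: DEFAULT_HYPERPARAMS)
    vote: str = "soft"

    def __post_init__(self) -> None:
        unknown = set(self.members) - set(MEMBER_NAMES)
        if unknown:
            raise ValueError(f"unknown ensemble members: {sorted(unknown)}")
        if not self.members:
            raise ValueError("ensemble needs at least one member")

    def build(self, seed: int) -> dict[str, object]:
        hp = {name: dict(DEFAULT_HYPERPARAMS[name]) for name in MEMBER_NAMES}
        for name, params in self.hyperparams.items():
            hp.setdefault(name, {}).update(params)
        builders = {
            # Platt-calibrated SVM: soft voting needs class probabilities
            "svm": lambda: Pipeline(
                [
                    ("scale", StandardScaler()),
                    (
                        "svc",
                        CalibratedClassifierCV(
                            SVC(random_state=seed, **hp["svm"]), ensemble=False
                        ),
                    ),
                ]
            ),
            "gbdt": lambda: GradientBoostingClassifier(random_state=seed, **hp["gbdt"]),
            "rf": lambda: RandomForestClassifier(random_state=seed, n_jobs=1, **hp["rf"]),
            "xgboost": lambda: XGBClassifier(
                random_state=seed,
                n_jobs=1,
                eval_metric="logloss",
                tree_method="hist",
                verbosity=0,
                **hp["xgboost"],
            ),
        }
        return {name: builders[name]() for name in self.members}


@dataclass
class TrainingSet:
    features: FeatureTable
    labels: np.ndarray
    positive_pairs: list[tuple[int, int]]
    negative_pairs: list[tuple[int, int]]
    seed: int


@dataclass
class TrainedEnsemble:
    spec: EnsembleSpec
    fitted: dict[str, object]
    feature_width: int
    seed: int

    def member_probabilities(self, X: np.ndarray) -> np.ndarray:
        """Positive-class probability of each member; shape (members, n)."""
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.feature_width:
            raise ValueError(
                f"feature width {X.shape[1]} != training width {self.feature_width}"
            )
        return np.vstack(
            [self.fitted[name].predict_proba(X)[:, 1] for name in self.spec.members]
        )

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return soft_vote(self.member_probabilities(X))


def sample_negatives(
    assoc: AssociationTable,
    count: int,
    seed: int,
    strategy: str = "uniform",
    exclude_disease: int | None = None,
) -> list[tuple[int, int]]:
    """Draw ``count`` distinct unknown pairs (A(i,j)=0) uniformly at random.

    ``exclude_disease`` removes one disease column from the sampling pool
    (used by the isolated-disease protocol).
    """
    if strategy != "uniform":
        raise ValueError(f"unknown negative-sampling strategy: {strategy}")
    mask = assoc.A == 0
    if exclude_disease is not None:
        mask[:, exclude_disease] = False
    zeros = np.argwhere(mask)
    if count > len(zeros):
        raise ValueError(f"requested {count} negatives but only {len(zeros)} unknown pairs")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(zeros), size=count, replace=False)
    return [tuple(ij) for ij in zeros[chosen]]


def build_training_set(
    assoc: AssociationTable,
    SM: SimilarityMatrix,
    SD: SimilarityMatrix,
    pca_models: tuple[PcaModel, PcaModel],
    mirna_corpus,
    disease_corpus,
    seed: int,
    neg_ratio: float = 1.0,
    top_k: int = 200,
    group_size: int = 50,
    exclude_disease: int | None = None,
    exclude_negative_pool: bool = True,
) -> TrainingSet:
    """Positives = known associations; negatives sampled from unknown pairs.

    ``exclude_disease`` drops that disease's column from the positives; by
    default (``exclude_negative_pool``) it is also removed from the
    negative-sampling pool so nothing about the column enters training.
    """
    positives = assoc.positive_pairs()
    if exclude_disease is not None:
        positives = [(i, j) for i, j in positives if j != exclude_disease]
    n_neg = int(round(neg_ratio * len(positives)))
    negatives = sample_negatives(
        assoc,
        n_neg,
        seed=seed,
        exclude_disease=exclude_disease if exclude_negative_pool else None,
    )
    pairs = positives + negatives
    labels = [1] * len(positives) + [0] * len(negatives)
    table = assemble_feature_table(
        pairs, labels, SM, SD, pca_models, mirna_corpus, disease_corpus,
        top_k=top_k, group_size=group_size,
    )
    return TrainingSet(
        features=table,
        labels=np.asarray(labels, dtype=int),
        positive_pairs=positives,
        negative_pairs=negatives,
        seed=seed,
    )


def soft_vote(member_probs: np.ndarray) -> np.ndarray:
    """Unweighted mean of the members' positive-class probabilities."""
    P = np.asarray(member_probs, dtype=float)
    if P.ndim != 2:
        raise ValueError("member_probs must be a 2-D (members x samples) array")
    if P.min(initial=0.0) < 0.0 or P.max(initial=0.0) > 1.0:
        raise ValueError("probabilities must lie in [0, 1]")
    return P.mean(axis=0)


def train_ensemble(train: TrainingSet, spec: EnsembleSpec | None = None) -> TrainedEnsemble:
    spec = spec or EnsembleSpec()
    X, y = train.features.values, train.labels
    return _fit(spec, X, y, train.seed)


def _fit(spec: EnsembleSpec, X: np.ndarray, y: np.ndarray, seed: int) -> TrainedEnsemble:
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training set contains a single class")
    if min(np.sum(y == c) for c in classes) < 2:
        raise ValueError("need at least 2 samples of each class")
    fitted = spec.build(seed)
    for est in fitted.values():
        est.fit(X, y)
    return TrainedEnsemble(spec=spec, fitted=fitted, feature_width=X.shape[1], seed=seed)


@dataclass
class PRF:
    precision: float
    recall: float
    f1: float
    undefined: frozenset[str] = frozenset()


def classification_metrics(
    labels: np.ndarray, scores: np.ndarray, threshold: float = 0.5
) -> PRF:
    """Precision, recall and F1 at a probability threshold.

    precision = TP/(TP+FP), recall = TP/(TP+FN), F1 their harmonic mean;
    a zero denominator yields 0 and the metric's name in ``undefined``.
    """
    y = np.asarray(labels).astype(int)
    pred = (np.asarray(scores, dtype=float) >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    undefined = set()
    if tp + fp == 0:
        precision = 0.0
        undefined.add("precision")
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        recall = 0.0
        undefined.add("recall")
    else:
        recall = tp / (tp + fn)
    if precision + recall == 0:
        f1 = 0.0
        undefined.add("f1")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return PRF(precision, recall, f1, frozenset(undefined))


def roc_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """ROC AUC as the Mann-Whitney concordance P(s⁺>s⁻) + ½P(s⁺=s⁻)."""
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC AUC needs both classes present")
    ranks = rankdata(s)  # midranks handle ties as half-concordances
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def pr_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Area under the precision-recall step curve (Σ precision·Δrecall over
    distinct-score thresholds, no interpolation)."""
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("PR AUC needs at least one positive")
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(1 - y_sorted)
    # evaluate only at the last index of each distinct score (the thresholds)
    last = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tp, fp = tp[last], fp[last]
    precision = tp / (tp + fp)
    recall = tp / n_pos
    d_recall = np.diff(np.r_[0.0, recall])
    return float(np.sum(precision * d_recall))


def roc_curve_points(labels: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """(FPR, TPR) points of the empirical ROC curve, one per threshold."""
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    order = np.argsort(-s, kind="stable")
    y_sorted, s_sorted = y[order], s[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(1 - y_sorted)
    last = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tpr = np.r_[0.0, tp[last] / max(1, y.sum())]
    fpr = np.r_[0.0, fp[last] / max(1, (1 - y).sum())]
    return np.column_stack([fpr, tpr])


def pr_curve_points(labels: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """(recall, precision) points of the PR step curve, one per threshold."""
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    order = np.argsort(-s, kind="stable")
    y_sorted, s_sorted = y[order], s[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(1 - y_sorted)
    last = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tp, fp = tp[last], fp[last]
    recall = tp / max(1, y.sum())
    precision = tp / (tp + fp)
    return np.column_stack([recall, precision])


@dataclass
class FoldMetrics:
    precision: float
    recall: float
    f1: float
    auc: float
    aupr: float


@dataclass
class CvReport:
    """Per-fold metrics plus their mean ± sd, and per-member fold AUCs."""

    folds: list[FoldMetrics]
    member_auc: dict[str, list[float]]
    roc_points: list[np.ndarray]
    pr_points: list[np.ndarray]
    folds_k: int
    repeats: int
    seed: int
    stratified: bool = True

    def _vals(self, name: str) -> np.ndarray:
        return np.array([getattr(f, name) for f in self.folds])

    def mean(self, name: str) -> float:
        return float(self._vals(name).mean())

    def std(self, name: str) -> float:
        return float(self._vals(name).std())

    def mean_member_auc(self) -> dict[str, float]:
        return {m: float(np.mean(v)) for m, v in self.member_auc.items()}

    def summary(self) -> dict:
        metrics = ("precision", "recall", "f1", "auc", "aupr")
        return {
            "folds": self.folds_k,
            "repeats": self.repeats,
            "seed": self.seed,
            "stratified": self.stratified,
            "per_fold": [
                {m: getattr(f, m) for m in metrics} for f in self.folds
            ],
            "average": {m: self.mean(m) for m in metrics},
            "std": {m: self.std(m) for m in metrics},
            "member_mean_auc": self.mean_member_auc(),
        }


def run_cross_validation(
    train: TrainingSet,
    spec: EnsembleSpec | None = None,
    folds: int = 5,
    repeats: int = 1,
    seed: int | None = None,
    threshold: float = 0.5,
) -> CvReport:
    """Stratified K-fold cross-validation of the soft-voting ensemble.

    Each repeat re-partitions with seed ``base + repeat`` and contributes
    ``folds`` fold entries; averages in the report run over all of them.
    Member-level AUCs are computed from the same fitted members the vote uses.
    """
    spec = spec or EnsembleSpec()
    if folds < 2:
        raise ValueError("folds must be >= 2")
    base = train.seed if seed is None else seed
    X, y = train.features.values, train.labels
    if min(np.sum(y == 1), np.sum(y == 0)) < folds:
        raise ValueError("fold count exceeds the size of a class")
    fold_metrics: list[FoldMetrics] = []
    member_auc: dict[str, list[float]] = {m: [] for m in spec.members}
    roc_pts, pr_pts = [], []
    for rep in range(repeats):
        rep_seed = base + rep
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rep_seed)
        for fold_idx, (tr, te) in enumerate(skf.split(X, y)):
            model = _fit(spec, X[tr], y[tr], seed=rep_seed)
            probs = model.member_probabilities(X[te])
            voted = soft_vote(probs)
            prf = classification_metrics(y[te], voted, threshold)
            fold_metrics.append(
                FoldMetrics(
                    prf.precision,
                    prf.recall,
                    prf.f1,
                    roc_auc(y[te], voted),
                    pr_auc(y[te], voted),
                )
            )
            for m_name, m_scores in zip(spec.members, probs):
                member_auc[m_name].append(roc_auc(y[te], m_scores))
            roc_pts.append(roc_curve_points(y[te], voted))
            pr_pts.append(pr_curve_points(y[te], voted))
    return CvReport(
        folds=fold_metrics,
        member_auc=member_auc,
        roc_points=roc_pts,
        pr_points=pr_pts,
        folds_k=folds,
        repeats=repeats,
        seed=base,
    )
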