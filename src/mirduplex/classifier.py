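"""Boosted random-forest scorer for candidate miRNA:miRNA* duplexes.

The binary classifier is an AdaBoost.M1 ensemble (reweighting, 10 rounds by
default) whose weak learner is a random forest of 50 unlimited-depth trees
with sqrt(100) = 10 features examined per split.  The model's score for a
candidate is the boosting-weighted vote fraction for the positive class,
which lies in [0, 1].

Evaluation follows the standard binary-classification metrics: sensitivity
SE = TP/(TP+FN), specificity SP = TN/(TN+FP), accuracy
ACC = (TP+TN)/total, Matthews correlation coefficient
MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)) (0 when any
factor of the denominator vanishes), and the area under the ROC curve,
equal to the normalized Mann-Whitney U statistic with ties counted half.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from . import features as _features
from .errors import ContractError, FingerprintMismatchError, TrainingError

N_FEATURES = 100


@dataclass(frozen=True)
class ModelParams:
    """Ensemble hyperparameters (defaults follow the reference configuration)."""

    n_trees: int = 50
    max_depth: Optional[int] = None  # unlimited
    boosting_rounds: int = 10
    base_seed: int = 1

    def with_seed(self, seed: int) -> "ModelParams":
        return replace(self, base_seed=seed)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ContractError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class Metrics:
    sensitivity: float
    specificity: float
    accuracy: float
    mcc: float
    auc: Optional[float] = None

    def as_dict(self) -> dict:
        d = {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "mcc": self.mcc,
        }
        if self.auc is not None:
            d["auc"] = self.auc
        return d


@dataclass
class DuplexModel:
    """A trained boosted ensemble plus the metadata needed to apply it safely."""

    ensemble: AdaBoostClassifier
    params: ModelParams
    fingerprint: str
    clade: str = "all"
    training_summary: dict = field(default_factory=dict)
    version: int = 1

    def _check(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != N_FEATURES:
            raise ContractError(f"expected {N_FEATURES}-feature vectors, got {X.shape[1]}")
        if self.fingerprint != _features.registry_fingerprint():
            raise FingerprintMismatchError(
                "model was trained against a different feature registry"
            )
        return X

    def score_matrix(self, X: np.ndarray) -> np.ndarray:
        """Boosting-weighted positive-vote fraction for each row, in [0, 1]."""
        X = self._check(X)
        ens = self.ensemble
        weights = np.asarray(ens.estimator_weights_[: len(ens.estimators_)], dtype=float)
        if weights.sum() <= 0:
            weights = np.ones(len(ens.estimators_))
        votes = np.zeros(X.shape[0])
        for w, est in zip(weights, ens.estimators_):
            votes += w * (est.predict(X) == 1)
        return votes / weights.sum()

    def score(self, fv: np.ndarray) -> float:
        return float(self.score_matrix(np.asarray(fv).reshape(1, -1))[0])


def train(
    matrix: np.ndarray,
    labels: Sequence[int],
    params: ModelParams = ModelParams(),
    clade: str = "all",
) -> DuplexModel:
    """Fit the boosted random forest; deterministic for a given base_seed."""
    X = np.asarray(matrix, dtype=np.float64)
    y = np.asarray(labels, dtype=int)
    if X.ndim != 2 or X.shape[1] != N_FEATURES:
        raise ContractError(f"training matrix must be (n, {N_FEATURES})")
    if len(np.unique(y)) < 2:
        raise TrainingError("training labels contain a single class")
    if len(y) < 20:
        raise TrainingError(f"need at least 20 examples, got {len(y)}")
    base = RandomForestClassifier(
        n_estimators=params.n_trees,
        max_depth=params.max_depth,
        max_features="sqrt",
        bootstrap=True,
        random_state=params.base_seed,
    )
    ens = AdaBoostClassifier(
        estimator=base,
        n_estimators=params.boosting_rounds,
        random_state=params.base_seed,
    )
    ens.fit(X, y)
    summary = {
        "n_examples": int(len(y)),
        "n_positive": int((y == 1).sum()),
        "n_negative": int((y == 0).sum()),
    }
    return DuplexModel(
        ensemble=ens,
        params=params,
        fingerprint=_features.registry_fingerprint(),
        clade=clade,
        training_summary=summary,
    )


def score(model: DuplexModel, fv: np.ndarray) -> float:
    return model.score(fv)


def confusion_metrics(c: ConfusionCounts) -> Metrics:
    """SE/SP/ACC/MCC from raw counts (AUC not derivable from counts)."""
    if c.total == 0:
        raise ContractError("all-zero confusion counts")
    se = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    sp = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else 0.0
    acc = (c.tp + c.tn) / c.total
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    mcc = 0.0 if denom == 0 else (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)
    return Metrics(se, sp, acc, mcc)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC = Mann-Whitney U / (n+ * n-), ties counted half."""
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ContractError("AUC needs both classes present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def counts_from_scores(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> ConfusionCounts:
    pred = np.asarray(scores) >= threshold
    y = np.asarray(labels).astype(bool)
    return ConfusionCounts(
        tp=int((pred & y).sum()),
        fp=int((pred & ~y).sum()),
        tn=int((~pred & ~y).sum()),
        fn=int((~pred & y).sum()),
    )


def cross_validate(
    matrix: np.ndarray,
    labels: Sequence[int],
    k: int = 10,
    seed: int = 1,
    params: ModelParams = ModelParams(),
    threshold: float = 0.5,
) -> Metrics:
    """Stratified k-fold CV; out-of-fold scores are pooled, thresholded for
    the confusion counts, and used directly for the AUC."""
    X = np.asarray(matrix, dtype=np.float64)
    y = np.asarray(labels, dtype=int)
    if k < 2:
        raise ContractError("k must be >= 2")
    _, class_counts = np.unique(y, return_counts=True)
    if len(class_counts) < 2:
        raise TrainingError("cross-validation needs both classes")
    if k > class_counts.min():
        raise ContractError(f"k={k} exceeds the smallest class size {class_counts.min()}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    oof = np.zeros(len(y))
    for train_idx, test_idx in skf.split(X, y):
        model = train(X[train_idx], y[train_idx], params=params.with_seed(seed))
        oof[test_idx] = model.score_matrix(X[test_idx])
    counts = counts_from_scores(oof, y, threshold)
    m = confusion_metrics(counts)
    return Metrics(m.sensitivity, m.specificity, m.accuracy, m.mcc, roc_auc(oof, y))
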