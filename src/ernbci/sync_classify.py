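"""Single-trial ERN vs. CRA classification with cross-validated evaluation.

Epochs are pooled across subjects, split with stratified 5-fold CV, and the
full feature chain (xDAWN -> augmented covariance -> tangent space -> L1 ->
PCA) plus the RBF-kernel SVM is refit per fold on training data only.
Chance level comes from the Zero-Rule classifier (constant majority-class
prediction); significance from a one-tailed Wilcoxon signed-rank test of the
per-fold accuracies against the per-fold chance accuracies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.stats
from sklearn.metrics import f1_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from ernbci.io_core import EpochSet, ValidationError
from ernbci.riemann_features import FeatureChain

logger = logging.getLogger("ernbci")


def train_classifier(features: np.ndarray, labels: np.ndarray,
                     c: float = 1.0, gamma="scale") -> SVC:
    """RBF-kernel SVM with class weights balanced by inverse frequency.

    ``gamma='scale'`` sets the kernel width to the reciprocal of
    (n_features x mean feature variance).
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValidationError("training set contains a single class")
    model = SVC(kernel="rbf", C=c, gamma=gamma, class_weight="balanced")
    model.fit(features, labels)
    return model


def zero_rule(train_labels: np.ndarray, val_labels: np.ndarray) -> float:
    """Accuracy of always predicting the training-set majority class."""
    values, counts = np.unique(np.asarray(train_labels), return_counts=True)
    majority = values[np.argmax(counts)]
    val_labels = np.asarray(val_labels)
    return float(np.mean(val_labels == majority))


def confusion_row_normalized(truth: np.ndarray, predictions: np.ndarray,
                             classes: tuple[str, str] = ("ERN", "CRA")
                             ) -> np.ndarray:
    """2x2 confusion matrix, rows indexed by truth and normalised to sum 1.

    A row without any true instances is returned as NaN (flagged empty).
    """
    truth = np.asarray(truth)
    predictions = np.asarray(predictions)
    mat = np.zeros((2, 2))
    for i, t in enumerate(classes):
        for j, p in enumerate(classes):
            mat[i, j] = np.sum((truth == t) & (predictions == p))
    sums = mat.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(sums > 0, mat / sums, np.nan)


def wilcoxon_exact_one_tailed(a, b) -> tuple[float, float]:
    """One-tailed (greater) Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; the p value uses the exact signed-rank
    null when sample size and ties permit, and the reported Z is the
    normal approximation of the negative-rank sum (the convention in which
    a significantly greater ``a`` yields a negative Z).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValidationError("all paired differences are zero")
    if n < 5:
        raise ValidationError("need >= 5 nonzero paired differences")
    res = scipy.stats.wilcoxon(d, alternative="greater",
                               method="exact" if n <= 25 else "approx")
    ranks = scipy.stats.rankdata(np.abs(d))
    w_minus = float(ranks[d < 0].sum())
    mu = n * (n + 1) / 4.0
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
    z = (w_minus - mu) / sigma
    return float(z), float(res.pvalue)


@dataclass
class FoldReport:
    """Per-fold metrics plus their aggregates and the significance test."""

    accuracy: list[float]
    auroc: list[float]
    f1: list[float]
    chance: list[float]
    confusion: np.ndarray                # row-normalised, pooled over folds
    wilcoxon_z: float
    wilcoxon_p: float
    seed: int | None = None

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracy))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.accuracy, ddof=1))

    @property
    def mean_auroc(self) -> float:
        return float(np.mean(self.auroc))

    @property
    def mean_f1(self) -> float:
        return float(np.mean(self.f1))

    @property
    def mean_chance(self) -> float:
        return float(np.mean(self.chance))

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "auroc": self.auroc, "f1": self.f1,
            "chance": self.chance,
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "mean_auroc": self.mean_auroc, "mean_f1": self.mean_f1,
            "mean_chance": self.mean_chance,
            "confusion": np.asarray(self.confusion).tolist(),
            "wilcoxon_z": self.wilcoxon_z, "wilcoxon_p": self.wilcoxon_p,
            "seed": self.seed,
        }


def crossval_5fold(epochs: np.ndarray | EpochSet,
                   labels: np.ndarray | None = None,
                   classes: tuple[str, str] = ("ERN", "CRA"),
                   n_folds: int = 5,
                   seed: int = 42,
                   svm_c: float = 1.0) -> FoldReport:
    """Stratified k-fold evaluation of the full chain, refit per fold."""
    if isinstance(epochs, EpochSet):
        labels = epochs.labels
        epochs = epochs.epochs
    epochs = np.asarray(epochs, float)
    labels = np.asarray(labels)
    for cls in classes:
        if np.sum(labels == cls) < n_folds:
            raise ValidationError(
                f"class {cls!r} has fewer members than folds")

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    acc, auc, f1s, chance = [], [], [], []
    pooled_truth, pooled_pred = [], []
    pos = classes[0]
    for train_idx, val_idx in skf.split(epochs, labels):
        chain = FeatureChain(classes=classes)
        x_train = chain.fit_transform(epochs[train_idx], labels[train_idx])
        x_val = chain.transform(epochs[val_idx])
        model = train_classifier(x_train, labels[train_idx], c=svm_c)
        pred = model.predict(x_val)
        truth = labels[val_idx]
        score = model.decision_function(x_val)
        if model.classes_[1] != pos:            # orient scores toward ERN
            score = -score
        acc.append(float(np.mean(pred == truth)))
        auc.append(float(roc_auc_score(truth == pos, score)))
        f1s.append(float(f1_score(truth, pred, pos_label=pos)))
        chance.append(zero_rule(labels[train_idx], truth))
        pooled_truth.extend(truth)
        pooled_pred.extend(pred)

    try:
        z, p = wilcoxon_exact_one_tailed(acc, chance)
    except ValidationError:
        # accuracies tied with chance in too many folds: trivially not
        # significant, report that instead of failing the whole evaluation
        z, p = float("nan"), 1.0
    report = FoldReport(acc, auc, f1s, chance,
                        confusion_row_normalized(pooled_truth, pooled_pred,
                                                 classes),
                        z, p, seed)
    logger.info("crossval_5fold: accuracy %.3f +/- %.3f (chance %.3f, "
                "Wilcoxon Z=%.3f p=%.4f)", report.mean_accuracy,
                report.sd_accuracy, report.mean_chance, z, p)
    return report
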