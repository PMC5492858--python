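"""Cross-validated evaluation of the recognizer.

10-fold stratified cross-validation over the feature corpus: each fold
trains the per-species mixtures on 90% of the data and labels the held
out 10%, accumulating a pooled confusion matrix (actual species on the
rows, predicted on the columns, rows normalised to percentages) and
per-fold per-class accuracies suitable for boxplots.

Two fold modes are provided. ``frame`` stratifies individual feature
vectors — the protocol implied by splitting "audio samples" — while
``clip`` keeps all frames of a recording on the same side of the split,
which avoids leaking intra-clip correlation into the test set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from .gmm import GMMSpeciesClassifier

# EM is monotone in exact arithmetic; allow this much relative float slack.
_EM_REL_SLACK = 1e-9


@dataclass
class FoldPlan:
    """Fold id per feature vector, stratified by class."""

    k: int
    assignment: np.ndarray
    mode: str
    seed: int

    def split(self):
        for fold in range(self.k):
            test = self.assignment == fold
            yield fold, ~test, test


@dataclass
class ConfusionMatrix:
    """Counts of actual (rows) vs predicted (columns) labels."""

    labels: list[str]
    counts: np.ndarray

    @property
    def row_percent(self) -> np.ndarray:
        """Rows rescaled to percentages (unrounded)."""
        return confusion_to_percent(self.counts)

    def to_frame(self, decimals: int | None = 2) -> pd.DataFrame:
        """Row-percentage table for display, rounded only here."""
        rp = self.row_percent
        if decimals is not None:
            rp = np.round(rp, decimals)
        return pd.DataFrame(rp, index=self.labels, columns=self.labels)

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / np.sum(self.counts))

    @property
    def per_class_accuracy(self) -> np.ndarray:
        return np.diag(self.counts) / self.counts.sum(axis=1)


@dataclass
class CVReport:
    """Everything the cross-validation measured."""

    labels: list[str]
    fold_class_accuracy: np.ndarray      # k x n
    pooled: ConfusionMatrix
    em_monotone: bool
    n_test_frames: int
    mode: str
    seed: int
    per_fold_predictions: list[tuple[np.ndarray, np.ndarray]] = field(
        default_factory=list, repr=False)  # (y_true, y_pred) per fold

    @property
    def mean_class_accuracy(self) -> np.ndarray:
        return self.fold_class_accuracy.mean(axis=0)

    @property
    def var_class_accuracy(self) -> np.ndarray:
        return self.fold_class_accuracy.var(axis=0)

    def boxplot_stats(self) -> pd.DataFrame:
        """min/q1/median/q3/max of per-fold accuracy for each class."""
        q = np.percentile(self.fold_class_accuracy, [0, 25, 50, 75, 100], axis=0)
        return pd.DataFrame(q.T, index=self.labels,
                            columns=["min", "q1", "median", "q3", "max"])

    def to_long_frame(self) -> pd.DataFrame:
        k, n = self.fold_class_accuracy.shape
        rows = [(f, self.labels[c], self.fold_class_accuracy[f, c])
                for f in range(k) for c in range(n)]
        return pd.DataFrame(rows, columns=["fold", "class", "accuracy"])


def make_folds(labels: np.ndarray, k: int = 10, mode: str = "frame",
               seed: int = 0, groups: np.ndarray | None = None) -> FoldPlan:
    """Stratified fold assignment, deterministic under ``seed``.

    ``frame`` mode stratifies vectors directly; ``clip`` mode requires
    ``groups`` (one clip id per vector) and never splits a clip across
    train and test.
    """
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError(f"k={k} leaves no held-out set; need k >= 2")
    classes, counts = np.unique(labels, return_counts=True)
    if mode == "frame":
        small = classes[counts < k]
        if small.size:
            raise ValueError(
                f"class {small[0]!r} has only {counts[counts < k][0]} vectors, "
                f"fewer than k={k} folds")
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split_iter = splitter.split(np.zeros(labels.size), labels)
    elif mode == "clip":
        if groups is None:
            raise ValueError("clip mode requires a groups array of clip ids")
        groups = np.asarray(groups)
        for cls in classes:
            n_clips = np.unique(groups[labels == cls]).size
            if n_clips < k:
                raise ValueError(
                    f"class {cls!r} has only {n_clips} clips, fewer than k={k}")
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
        split_iter = splitter.split(np.zeros(labels.size), labels, groups)
    else:
        raise ValueError(f"unknown fold mode {mode!r}")
    assignment = np.full(labels.size, -1)
    for fold, (_, test_idx) in enumerate(split_iter):
        assignment[test_idx] = fold
    return FoldPlan(k=k, assignment=assignment, mode=mode, seed=seed)


def confusion_to_percent(counts: np.ndarray) -> np.ndarray:
    """Row-normalise confusion counts to percentages (rows sum to 100)."""
    counts = np.asarray(counts, dtype=np.float64)
    sums = counts.sum(axis=1)
    if np.any(sums == 0):
        empty = int(np.argmin(sums))
        raise ValueError(f"confusion matrix row {empty} has no observations")
    return counts / sums[:, None] * 100.0


def _history_monotone(history: list[float]) -> bool:
    h = np.asarray(history)
    if h.size < 2:
        return True
    slack = _EM_REL_SLACK * np.maximum(np.abs(h[:-1]), 1.0)
    return bool(np.all(np.diff(h) >= -slack))


def run_cv(X: np.ndarray, y: np.ndarray, plan: FoldPlan | None = None,
           classifier: GMMSpeciesClassifier | None = None, k: int = 10,
           mode: str = "frame", seed: int = 0,
           groups: np.ndarray | None = None, **gmm_params) -> CVReport:
    """Train/test the per-species GMM bank over every fold.

    Any ``gmm_params`` are forwarded to :class:`GMMSpeciesClassifier`
    when no classifier prototype is supplied. EM monotonicity is checked
    on every per-class fit of every fold and reported on the result.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    y = np.asarray(y)
    if plan is None:
        plan = make_folds(y, k=k, mode=mode, seed=seed, groups=groups)
    if classifier is None:
        classifier = GMMSpeciesClassifier(random_state=seed, **gmm_params)
    classes = np.unique(y)
    n = classes.size
    fold_acc = np.zeros((plan.k, n))
    pooled = np.zeros((n, n), dtype=np.int64)
    monotone = True
    predictions = []
    for fold, train_mask, test_mask in plan.split():
        clf = clone(classifier)
        try:
            clf.fit(X[train_mask], y[train_mask])
        except Exception as exc:
            raise RuntimeError(f"training failed in fold {fold}: {exc}") from exc
        y_pred = clf.predict(X[test_mask])
        y_true = y[test_mask]
        cm = _sk_confusion(y_true, y_pred, labels=classes)
        pooled += cm
        with np.errstate(invalid="ignore"):
            fold_acc[fold] = np.diag(cm) / cm.sum(axis=1)
        monotone &= all(_history_monotone(h) for h in clf.em_histories().values())
        predictions.append((y_true, y_pred))
    return CVReport(
        labels=[str(c) for c in classes], fold_class_accuracy=fold_acc,
        pooled=ConfusionMatrix(labels=[str(c) for c in classes], counts=pooled),
        em_monotone=monotone, n_test_frames=int(pooled.sum()),
        mode=plan.mode, seed=plan.seed, per_fold_predictions=predictions)
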