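"""Random-forest classifier over the selected descriptors: OOB-driven
tree-count choice, stratified cross-validated performance, and class
probabilities for screening.

The ensemble itself is scikit-learn's ``RandomForestClassifier``; this
module owns the out-of-bag tree-count rule (smallest forest whose OOB
error is within a tolerance of the curve minimum), the stratified-fold
evaluation layout, and the report containers.
"""

from __future__ import annotations

import logging
import pickle
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold

from .core_io import DescriptorMatrix, LabeledDrugSet, normalize_id

logger = logging.getLogger("crosstalk")

__all__ = ["TrainedClassifier", "CVReport", "OOBCurve", "labels_vector",
           "train_classifier", "oob_curve", "cross_validate",
           "predict_probabilities"]

POSITIVE, NEGATIVE = "positive", "negative"


def labels_vector(m: DescriptorMatrix, labels: LabeledDrugSet) -> np.ndarray:
    """Align the labeled drug set with the matrix rows -> array of class names."""
    pos = {normalize_id(d) for d in labels.positives}
    neg = {normalize_id(d) for d in labels.negatives}
    out = []
    for mol in m.molecule_ids:
        key = normalize_id(mol)
        if key in pos:
            out.append(POSITIVE)
        elif key in neg:
            out.append(NEGATIVE)
        else:
            raise KeyError(f"molecule {mol!r} has no class label")
    return np.array(out)


def _clean_matrix(m: DescriptorMatrix, feature_names: list[str] | None = None) -> np.ndarray:
    if feature_names is not None:
        missing = [f for f in feature_names if f not in m.feature_names]
        if missing:
            raise KeyError(f"matrix lacks required feature(s): {missing}")
        frame = m.frame.loc[:, feature_names]
    else:
        frame = m.frame
    if frame.isna().any().any():
        bad = frame.columns[frame.isna().any()].tolist()
        raise ValueError(f"missing values in feature(s) {bad}; impute or drop first")
    return frame.to_numpy(dtype=float)


@dataclass
class TrainedClassifier:
    """A fitted forest plus the metadata needed to apply it elsewhere."""

    feature_names: list[str]
    n_trees: int
    rng_seed: int
    estimator: RandomForestClassifier
    class_counts: dict[str, int]

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path: str | Path) -> "TrainedClassifier":
        with open(path, "rb") as fh:
            return pickle.load(fh)


@dataclass
class CVReport:
    """Fold-wise and pooled performance of the stratified cross-validation."""

    fold_accuracies: list[float]
    overall_accuracy: float          # pooled correct / total
    mean_fold_accuracy: float
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    confusion: pd.DataFrame          # rows = true class, cols = predicted
    n_folds: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = [("overall_accuracy", self.overall_accuracy),
                ("mean_fold_accuracy", self.mean_fold_accuracy)]
        rows += [(f"fold{i+1}_accuracy", a) for i, a in enumerate(self.fold_accuracies)]
        for cls in (NEGATIVE, POSITIVE):
            rows += [(f"{cls}_precision", self.precision[cls]),
                     (f"{cls}_recall", self.recall[cls]),
                     (f"{cls}_f1", self.f1[cls])]
        return pd.DataFrame(rows, columns=["metric", "value"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class OOBCurve:
    """Out-of-bag error as a function of forest size."""

    tree_counts: list[int]
    oob_errors: list[float]
    chosen_n_trees: int
    tolerance: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"n_trees": self.tree_counts, "oob_error": self.oob_errors})

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _check_class_sizes(y: np.ndarray, minimum: int = 2) -> None:
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < minimum:
        raise ValueError(
            f"need >= {minimum} drugs in each of two classes, got "
            f"{dict(zip(classes, counts))}"
        )


def train_classifier(
    m: DescriptorMatrix,
    labels: LabeledDrugSet,
    *,
    n_trees: int = 100,
    seed: int = 0,
    **rf_kwargs,
) -> TrainedClassifier:
    """Fit the forest on all labeled drugs."""
    y = labels_vector(m, labels)
    _check_class_sizes(y)
    X = _clean_matrix(m)
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, **rf_kwargs)
    rf.fit(X, y)
    counts = {c: int((y == c).sum()) for c in np.unique(y)}
    return TrainedClassifier(list(m.feature_names), n_trees, seed, rf, counts)


def oob_curve(
    m: DescriptorMatrix,
    labels: LabeledDrugSet,
    *,
    max_trees: int = 200,
    step: int = 5,
    seed: int = 0,
    tolerance: float = 0.005,
) -> OOBCurve:
    """OOB error vs forest size, grown incrementally with warm starts.

    The chosen size is the smallest forest whose OOB error is within
    ``tolerance`` of the curve minimum.  Early small forests can leave some
    samples never out-of-bag; their error is computed over the covered
    samples (scikit-learn warns and scores what it can).
    """
    y = labels_vector(m, labels)
    _check_class_sizes(y)
    X = _clean_matrix(m)
    rf = RandomForestClassifier(
        n_estimators=0, warm_start=True, oob_score=True,
        bootstrap=True, random_state=seed,
    )
    counts, errors = [], []
    grid = list(range(step, max_trees + 1, step)) or [max_trees]
    for n in grid:
        rf.set_params(n_estimators=n)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # few-tree OOB coverage warning
            rf.fit(X, y)
        counts.append(n)
        errors.append(float(1.0 - rf.oob_score_))
    best = min(errors)
    chosen = next(n for n, e in zip(counts, errors) if e <= best + tolerance)
    logger.info("oob_curve: min error %.4f, chosen n_trees=%d (tol %.3f)",
                best, chosen, tolerance)
    return OOBCurve(counts, errors, chosen, tolerance)


def cross_validate(
    m: DescriptorMatrix,
    labels: LabeledDrugSet,
    *,
    n_folds: int = 5,
    seed: int = 0,
    n_trees: int = 100,
) -> CVReport:
    """Stratified k-fold evaluation; every drug is tested exactly once.

    The pooled accuracy (all out-of-fold predictions against truth) is the
    headline number; the mean of fold accuracies is reported alongside.
    """
    y = labels_vector(m, labels)
    _check_class_sizes(y, minimum=n_folds)
    X = _clean_matrix(m)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    predictions = np.empty_like(y)
    fold_acc = []
    for k, (train_idx, test_idx) in enumerate(skf.split(X, y)):
        rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed + k)
        rf.fit(X[train_idx], y[train_idx])
        pred = rf.predict(X[test_idx])
        predictions[test_idx] = pred
        fold_acc.append(float((pred == y[test_idx]).mean()))

    overall = float((predictions == y).mean())
    classes = [NEGATIVE, POSITIVE]
    prec, rec, f1, _ = precision_recall_fscore_support(
        y, predictions, labels=classes, zero_division=0.0
    )
    conf = pd.DataFrame(
        confusion_matrix(y, predictions, labels=classes),
        index=classes, columns=classes,
    )
    return CVReport(
        fold_accuracies=fold_acc,
        overall_accuracy=overall,
        mean_fold_accuracy=float(np.mean(fold_acc)),
        precision=dict(zip(classes, map(float, prec))),
        recall=dict(zip(classes, map(float, rec))),
        f1=dict(zip(classes, map(float, f1))),
        confusion=conf,
        n_folds=n_folds,
        seed=seed,
    )


def predict_probabilities(
    model: TrainedClassifier, m: DescriptorMatrix
) -> pd.DataFrame:
    """Per-drug class probabilities (columns 'positive'/'negative', sum 1)."""
    X = _clean_matrix(m, model.feature_names)
    proba = model.estimator.predict_proba(X)
    out = pd.DataFrame(proba, index=m.molecule_ids, columns=model.estimator.classes_)
    for cls in (POSITIVE, NEGATIVE):  # a degenerate fit can know one class only
        if cls not in out.columns:
            out[cls] = 0.0
    return out[[POSITIVE, NEGATIVE]]
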