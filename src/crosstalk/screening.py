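"""Applicability-domain-filtered screening of an external drug library.

The library passes through four attrition stages before ranking:

1. atom-count filter — drugs with fewer than ``natom_min`` atoms go;
2. missing-feature drop — drugs lacking any selected descriptor value go;
3. leverage filter — drugs whose leverage h_i = x_i^T (X^T X)^-1 x_i
   exceeds the warning leverage h* = multiplier * (|F| + 1) / n go.  By
   default the basis X and the count n are the screened library itself
   (``ad_basis='screening'``), which mirrors the study's printed
   arithmetic; the textbook QSAR convention (the training matrix as basis)
   is available as ``ad_basis='training'``;
4. one-class SVM (RBF) novelty filter against the training drugs, on
   descriptors standardized with training statistics.

Survivors are ranked by the classifier's class probabilities; a drug makes
the candidate table only if its larger class probability meets the
threshold (0.95 by default).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.svm import OneClassSVM

from .classify import NEGATIVE, POSITIVE, TrainedClassifier, predict_probabilities
from .core_io import DescriptorMatrix, PipelineConfig

logger = logging.getLogger("crosstalk")

__all__ = ["ScreeningReport", "CandidateTable", "natom_filter",
           "warning_leverage", "leverage", "leverages", "leverage_filter",
           "ocsvm_filter", "rank_candidates", "run_screening"]


@dataclass
class ScreeningReport:
    """Per-stage attrition of the screened library; counts must reconcile."""

    n_input: int
    removed_small_molecules: list[str]
    removed_missing_features: list[str]
    warning_leverage: float
    leverages: dict[str, float]
    removed_high_leverage: list[str]
    removed_ocsvm: list[str]
    retained: list[str]
    ad_basis: str
    seed: int

    def __post_init__(self) -> None:
        stages = [self.removed_small_molecules, self.removed_missing_features,
                  self.removed_high_leverage, self.removed_ocsvm, self.retained]
        total = sum(len(s) for s in stages)
        union = set().union(*map(set, stages))
        if total != self.n_input or len(union) != total:
            raise ValueError("screening stages must partition the input library")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                ("input", self.n_input),
                ("removed_small_molecules", len(self.removed_small_molecules)),
                ("removed_missing_features", len(self.removed_missing_features)),
                ("removed_high_leverage", len(self.removed_high_leverage)),
                ("removed_ocsvm", len(self.removed_ocsvm)),
                ("retained", len(self.retained)),
            ],
            columns=["stage", "count"],
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class CandidateTable:
    """Thresholded candidates: (drug, predicted label, probability) rows,
    sorted descending by probability within each label."""

    rows: pd.DataFrame  # columns: drug_id, label, probability

    def __post_init__(self) -> None:
        expected = ["drug_id", "label", "probability"]
        if list(self.rows.columns) != expected:
            raise ValueError(f"candidate table must have columns {expected}")

    @property
    def positives(self) -> pd.DataFrame:
        return self.rows[self.rows.label == POSITIVE]

    @property
    def negatives(self) -> pd.DataFrame:
        return self.rows[self.rows.label == NEGATIVE]

    def to_tsv(self, path: str | Path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)


def natom_filter(
    m: DescriptorMatrix, natom_min: int = 7
) -> tuple[DescriptorMatrix, list[str]]:
    """Remove very small molecules: atom count below ``natom_min``.

    A drug with a missing atom count is kept here (it will fall to the
    missing-feature stage if the atom count is among the model features).
    """
    if m.natom_column is None:
        raise ValueError("descriptor matrix has no atom-count column")
    if m.shape[0] == 0:
        return m, []
    col = m.frame[m.natom_column]
    removed = [i for i in m.molecule_ids if pd.notna(col[i]) and col[i] < natom_min]
    keep = [i for i in m.molecule_ids if i not in set(removed)]
    return m.subset_molecules(keep), removed


def warning_leverage(n_features: int, n_compounds: int, multiplier: float = 3.0) -> float:
    """h* = multiplier * (p) / n with p = number of model variables + 1."""
    if n_compounds <= 0:
        raise ValueError("n_compounds must be positive")
    return multiplier * (n_features + 1) / n_compounds


def leverages(query: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Leverage h_i of each query row against the basis matrix.

    h_i = x_i^T (X^T X)^-1 x_i.  A rank-deficient X^T X falls back to the
    Moore-Penrose pseudo-inverse with a logged warning.
    """
    X = np.asarray(basis, dtype=float)
    Q = np.atleast_2d(np.asarray(query, dtype=float))
    if Q.shape[1] != X.shape[1]:
        raise ValueError(
            f"dimension mismatch: query has {Q.shape[1]} columns, basis {X.shape[1]}"
        )
    gram = X.T @ X
    if np.linalg.matrix_rank(gram) < gram.shape[0]:
        logger.warning("rank-deficient X^T X; using pseudo-inverse for leverage")
        inv = np.linalg.pinv(gram)
    else:
        inv = np.linalg.inv(gram)
    return np.einsum("ij,jk,ik->i", Q, inv, Q)


def leverage(x: np.ndarray, basis: np.ndarray) -> float:
    """Leverage of a single descriptor row (see :func:`leverages`)."""
    return float(leverages(np.asarray(x, dtype=float)[None, :], basis)[0])


def leverage_filter(
    screen: DescriptorMatrix,
    *,
    train: DescriptorMatrix | None = None,
    ad_basis: str = "screening",
    multiplier: float = 3.0,
) -> tuple[DescriptorMatrix, list[str], float, dict[str, float]]:
    """Apply the warning-leverage cut; returns (kept, removed, h*, h_i)."""
    if ad_basis == "screening":
        basis = screen.frame.to_numpy(dtype=float)
        n = screen.shape[0]
    elif ad_basis == "training":
        if train is None:
            raise ValueError("ad_basis='training' requires the training matrix")
        basis = train.frame.to_numpy(dtype=float)
        n = train.shape[0]
    else:
        raise ValueError("ad_basis must be 'screening' or 'training'")
    if screen.shape[0] == 0:
        return screen, [], float("nan"), {}
    h_star = warning_leverage(screen.shape[1], n, multiplier)
    h = leverages(screen.frame.to_numpy(dtype=float), basis)
    h_by_drug = dict(zip(screen.molecule_ids, map(float, h)))
    removed = [i for i, hi in h_by_drug.items() if hi > h_star]
    keep = [i for i in screen.molecule_ids if i not in set(removed)]
    return screen.subset_molecules(keep), removed, h_star, h_by_drug


def ocsvm_filter(
    train: DescriptorMatrix,
    screen: DescriptorMatrix,
    *,
    nu: float = 0.1,
    gamma: float | None = None,
) -> tuple[DescriptorMatrix, list[str]]:
    """One-class SVM (RBF) novelty filter against the training drugs.

    Both matrices are standardized with the training mean/SD.  ``gamma``
    defaults to 1 / (n_features * pooled variance of the standardized
    training matrix).  Returns (kept screen subset, removed ids).
    """
    Xt = train.frame.loc[:, screen.feature_names].to_numpy(dtype=float)
    if np.isnan(Xt).any():
        raise ValueError("training matrix has missing values")
    mu, sd = Xt.mean(axis=0), Xt.std(axis=0, ddof=0)
    if (sd == 0).any():
        bad = [f for f, s in zip(screen.feature_names, sd) if s == 0]
        raise ValueError(f"zero-variance training feature(s): {bad}")
    Zt = (Xt - mu) / sd
    if gamma is None:
        gamma = 1.0 / (Zt.shape[1] * Zt.var(ddof=0))
    clf = OneClassSVM(kernel="rbf", nu=nu, gamma=gamma)
    clf.fit(Zt)
    if screen.shape[0] == 0:
        return screen, []
    Zs = (screen.frame.to_numpy(dtype=float) - mu) / sd
    inlier = clf.predict(Zs) == 1
    keep = [i for i, ok in zip(screen.molecule_ids, inlier) if ok]
    removed = [i for i, ok in zip(screen.molecule_ids, inlier) if not ok]
    return screen.subset_molecules(keep), removed


def rank_candidates(
    model: TrainedClassifier,
    screen: DescriptorMatrix,
    threshold: float = 0.95,
) -> CandidateTable:
    """Threshold the larger class probability and sort within each label."""
    if not 0.5 < threshold <= 1:
        raise ValueError("threshold must be in (0.5, 1]")
    if screen.shape[0] == 0:
        return CandidateTable(pd.DataFrame(columns=["drug_id", "label", "probability"]))
    proba = predict_probabilities(model, screen.subset_features(model.feature_names))
    label = np.where(proba[POSITIVE] >= proba[NEGATIVE], POSITIVE, NEGATIVE)
    best = proba.max(axis=1)
    rows = pd.DataFrame(
        {"drug_id": proba.index, "label": label, "probability": best.to_numpy()}
    )
    rows = rows[rows.probability >= threshold]
    rows = rows.sort_values(
        ["label", "probability", "drug_id"], ascending=[False, False, True]
    ).reset_index(drop=True)
    return CandidateTable(rows)


def run_screening(
    model: TrainedClassifier,
    train: DescriptorMatrix,
    screen_library: DescriptorMatrix,
    config: PipelineConfig | None = None,
) -> tuple[ScreeningReport, CandidateTable]:
    """All four attrition stages followed by probability ranking.

    ``train`` must already be restricted to the model's features;
    ``screen_library`` is the raw descriptor matrix of the library (with
    its atom-count column).
    """
    cfg = config or PipelineConfig()
    n_input = screen_library.shape[0]

    after_natom, small = natom_filter(screen_library, cfg.natom_min)

    # restrict to the model features; drop drugs with any missing value there
    feats = model.feature_names
    missing_cols = [f for f in feats if f not in after_natom.feature_names]
    if missing_cols:
        raise KeyError(f"screen library lacks model feature(s): {missing_cols}")
    sub = after_natom.subset_features(feats)
    has_gap = sub.frame.isna().any(axis=1)
    missing_ids = list(sub.frame.index[has_gap])
    sub = sub.subset_molecules([i for i in sub.molecule_ids if i not in set(missing_ids)])

    train_f = train.subset_features(feats)
    kept_lev, high_lev, h_star, h_all = leverage_filter(
        sub, train=train_f, ad_basis=cfg.ad_basis, multiplier=cfg.leverage_multiplier
    )
    kept_svm, svm_removed = ocsvm_filter(
        train_f, kept_lev, nu=cfg.ocsvm_nu, gamma=cfg.ocsvm_gamma
    )
    report = ScreeningReport(
        n_input=n_input,
        removed_small_molecules=small,
        removed_missing_features=missing_ids,
        warning_leverage=h_star,
        leverages=h_all,
        removed_high_leverage=high_lev,
        removed_ocsvm=svm_removed,
        retained=list(kept_svm.molecule_ids),
        ad_basis=cfg.ad_basis,
        seed=cfg.rng_seed,
    )
    logger.info(
        "screening: %d -> small -%d, missing -%d, leverage -%d (h*=%.4g), "
        "ocsvm -%d => %d retained",
        n_input, len(small), len(missing_ids), len(high_lev), h_star,
        len(svm_removed), len(report.retained),
    )
    candidates = rank_candidates(model, kept_svm, cfg.probability_threshold)
    return report, candidates
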