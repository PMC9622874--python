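"""Four-stage filter cascade reducing a descriptor matrix to the feature
set separating therapeutic from exacerbating drugs.

Stages, in order:

1. drop constant descriptors (single distinct non-missing value);
2. prune highly correlated descriptors (|Pearson r| > cutoff, removing the
   member of each offending pair with the larger mean absolute correlation
   — the classic single-pass heuristic of caret's ``findCorrelation`` in
   its non-exact mode, correlations not recomputed after drops);
3. drop low-entropy descriptors (plug-in Shannon entropy in nats over an
   equal-width histogram below a threshold);
4. keep descriptors whose two-sample t-test between the two drug classes
   has p below alpha (Welch by default, pooled-variance optional; raw
   p-values, no multiplicity correction, with a Benjamini-Hochberg switch
   available).

Missing values: correlations use pairwise-complete observations; entropy
and t-tests ignore missing entries feature-wise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import DescriptorMatrix, LabeledDrugSet, PipelineConfig, normalize_id

logger = logging.getLogger("crosstalk")

__all__ = [
    "FeatureSelectionReport",
    "remove_constant",
    "prune_correlated",
    "shannon_entropy",
    "entropy_filter",
    "ttest_filter",
    "select_features",
]


@dataclass
class FeatureSelectionReport:
    """Fate of every input descriptor across the four cascade stages."""

    n_input_features: int
    removed_constant: list[str]
    removed_correlated: list[str]
    removed_low_entropy: list[str]
    removed_nonsignificant: list[str]
    selected: list[str]
    entropies: dict[str, float] = field(default_factory=dict)
    p_values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        parts = (
            self.removed_constant + self.removed_correlated
            + self.removed_low_entropy + self.removed_nonsignificant + self.selected
        )
        if len(parts) != self.n_input_features or len(set(parts)) != len(parts):
            raise ValueError("stage lists must partition the input feature names")

    def to_frame(self) -> pd.DataFrame:
        fate = {}
        for name in self.removed_constant:
            fate[name] = "removed_constant"
        for name in self.removed_correlated:
            fate[name] = "removed_correlated"
        for name in self.removed_low_entropy:
            fate[name] = "removed_low_entropy"
        for name in self.removed_nonsignificant:
            fate[name] = "removed_nonsignificant"
        for name in self.selected:
            fate[name] = "selected"
        return pd.DataFrame(
            {
                "feature": list(fate),
                "fate": [fate[n] for n in fate],
                "entropy": [self.entropies.get(n, np.nan) for n in fate],
                "p_value": [self.p_values.get(n, np.nan) for n in fate],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def remove_constant(m: DescriptorMatrix) -> tuple[DescriptorMatrix, list[str]]:
    """Drop descriptors with a single distinct non-missing value.

    All-missing columns count as constant.  Missing entries are ignored
    when judging constancy, so a column that is constant except for gaps
    still goes.
    """
    if m.shape[0] < 2:
        raise ValueError("need at least 2 molecules to judge constancy")
    nunique = m.frame.nunique(dropna=True)
    removed = [c for c in m.feature_names if nunique[c] <= 1]
    if len(removed) == len(m.feature_names):
        raise ValueError("every descriptor is constant; nothing to select from")
    return m.drop_features(removed), removed


def prune_correlated(
    m: DescriptorMatrix, cutoff: float = 0.9
) -> tuple[DescriptorMatrix, list[str]]:
    """Single-pass mean-absolute-correlation pruning of |r| > cutoff pairs.

    Pairwise-complete Pearson correlations are computed once.  Every
    upper-triangle pair above the cutoff flags one member for removal: the
    one with the larger mean absolute correlation over all columns (ties
    flag the earlier column).  Correlations are not recomputed after
    drops — the behaviour of the classic non-exact heuristic, which can
    therefore over-remove relative to an iterative re-check.
    """
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must be in (0, 1]")
    corr = m.frame.corr(method="pearson", min_periods=2).abs()
    acorr = corr.to_numpy(dtype=float, copy=True)
    np.fill_diagonal(acorr, np.nan)
    with np.errstate(invalid="ignore"):
        mean_abs = np.nanmean(acorr, axis=0)
    cols = list(corr.columns)
    flagged: set[int] = set()
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            r = acorr[i, j]
            if np.isnan(r) or r <= cutoff:
                continue
            flagged.add(j if mean_abs[j] > mean_abs[i] else i)
    removed = [cols[i] for i in sorted(flagged)]
    return m.drop_features(removed), removed


def shannon_entropy(values: np.ndarray, n_bins: int = 10) -> float:
    """Plug-in Shannon entropy (nats) of an equal-width histogram.

    The histogram spans the observed non-missing range; a zero-range
    (constant) feature has entropy 0.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        return 0.0
    lo, hi = x.min(), x.max()
    if lo == hi:
        return 0.0
    counts, _ = np.histogram(x, bins=n_bins, range=(lo, hi))
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def entropy_filter(
    m: DescriptorMatrix, theta: float = 1.5, n_bins: int = 10
) -> tuple[DescriptorMatrix, list[str], dict[str, float]]:
    """Drop descriptors whose histogram entropy falls below ``theta`` nats."""
    entropies = {
        c: shannon_entropy(m.frame[c].to_numpy(), n_bins) for c in m.feature_names
    }
    removed = [c for c in m.feature_names if entropies[c] < theta]
    return m.drop_features(removed), removed, entropies


def ttest_filter(
    m: DescriptorMatrix,
    labels: LabeledDrugSet,
    alpha: float = 0.05,
    *,
    welch: bool = True,
    fdr: bool = False,
) -> tuple[list[str], dict[str, float]]:
    """Two-sample t-test per descriptor between the two drug classes.

    Returns ``(selected_names, p_values)``.  Rows with a missing value in a
    descriptor are excluded from that descriptor's test only.  ``fdr=True``
    switches the alpha comparison to Benjamini-Hochberg adjusted p-values
    (off by default).
    """
    pos_keys = {normalize_id(d) for d in labels.positives}
    neg_keys = {normalize_id(d) for d in labels.negatives}
    idx_keys = [normalize_id(i) for i in m.molecule_ids]
    unlabeled = [i for i, k in zip(m.molecule_ids, idx_keys) if k not in pos_keys | neg_keys]
    if unlabeled:
        raise ValueError(f"molecules without a class label: {unlabeled}")
    is_pos = np.array([k in pos_keys for k in idx_keys])
    if is_pos.sum() < 2 or (~is_pos).sum() < 2:
        raise ValueError("each class needs at least 2 members for a t-test")

    p_values: dict[str, float] = {}
    for c in m.feature_names:
        x = m.frame[c].to_numpy()
        a, b = x[is_pos], x[~is_pos]
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        if a.size < 2 or b.size < 2 or (np.ptp(x[~np.isnan(x)]) == 0):
            p_values[c] = 1.0
            continue
        res = stats.ttest_ind(a, b, equal_var=not welch)
        p_values[c] = 1.0 if np.isnan(res.pvalue) else float(res.pvalue)

    names = list(p_values)
    crit = np.array([p_values[c] for c in names])
    if fdr:
        reject, *_ = multipletests(crit, alpha=alpha, method="fdr_bh")
        selected = [c for c, r in zip(names, reject) if r]
    else:
        selected = [c for c, p in zip(names, crit) if p < alpha]
    return selected, p_values


def select_features(
    m: DescriptorMatrix,
    labels: LabeledDrugSet,
    config: PipelineConfig | None = None,
) -> tuple[DescriptorMatrix, FeatureSelectionReport]:
    """Run the full four-stage cascade and report every descriptor's fate."""
    cfg = config or PipelineConfig()
    n_input = len(m.feature_names)

    m1, const = remove_constant(m)
    m2, corr = prune_correlated(m1, cfg.correlation_cutoff)
    m3, lowent, entropies = entropy_filter(m2, cfg.entropy_threshold, cfg.entropy_bins)
    selected, p_values = ttest_filter(m3, labels, cfg.alpha, welch=cfg.welch)
    nonsig = [c for c in m3.feature_names if c not in set(selected)]

    report = FeatureSelectionReport(
        n_input_features=n_input,
        removed_constant=const,
        removed_correlated=corr,
        removed_low_entropy=lowent,
        removed_nonsignificant=nonsig,
        selected=selected,
        entropies=entropies,
        p_values=p_values,
    )
    logger.info(
        "select_features: %d -> constant -%d, correlated -%d, low-entropy -%d, "
        "non-significant -%d => |F|=%d",
        n_input, len(const), len(corr), len(lowent), len(nonsig), len(selected),
    )
    return m.subset_features(selected), report
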