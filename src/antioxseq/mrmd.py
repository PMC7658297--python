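"""MRMD (Max-Relevance-Max-Distance) feature ranking and subset selection.

Each feature F_i of a labeled matrix gets two scores:

* relevance  MR_i = |PCC(F_i, C)| — absolute Pearson correlation with
  the 0/1 class vector C;
* distance   MD_i = (1 / (M - 1)) * sum_{k != i} ||F_i - F_k||_2 — mean
  Euclidean distance of the feature column to every other column, a
  redundancy penalty (larger = more independent).

The MRMD score is MR_i + MD_i; features are ranked by descending score
(stable, ties keep original column order).  By default feature columns
are min-max scaled to [0, 1] before the distance term so MR (bounded by
1) and MD live on commensurate scales; ``scale="none"`` gives the
literal unscaled form.

Subset selection is incremental: features are added in rank order (in
blocks of ``step``), each candidate subset is scored by stratified
k-fold cross-validated random-forest accuracy, and the smallest subset
attaining the maximal accuracy wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .sequence_io import FeatureMatrix


def pearson_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation coefficient in [-1, 1].

    Returns 0.0 (with a warning) when either vector has zero variance,
    where the coefficient is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"vectors must be 1-D of equal length, got {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = np.sqrt((dx * dx).sum())
    sy = np.sqrt((dy * dy).sum())
    if sx == 0.0 or sy == 0.0:
        warnings.warn("zero-variance vector: Pearson correlation undefined, returning 0")
        return 0.0
    return float((dx * dy).sum() / (sx * sy))


def mr_scores(fm: FeatureMatrix) -> np.ndarray:
    """Relevance MR_i = |PCC(F_i, C)| per feature (0 for constant columns)."""
    if fm.labels is None:
        raise ValueError("relevance scores require a labeled matrix")
    c = fm.labels.astype(float)
    out = np.empty(fm.n_features)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for j in range(fm.n_features):
            out[j] = abs(pearson_correlation(fm.values[:, j], c))
    return out


def _minmax_columns(x: np.ndarray) -> np.ndarray:
    lo = x.min(axis=0)
    span = x.max(axis=0) - lo
    span[span == 0] = 1.0  # constant columns map to 0
    return (x - lo) / span


def md_scores(fm: FeatureMatrix, scale: str = "minmax") -> np.ndarray:
    """Mean Euclidean distance of each feature column to all others."""
    if scale not in ("minmax", "none"):
        raise ValueError(f"scale must be 'minmax' or 'none', got {scale!r}")
    m = fm.n_features
    if m < 2:
        raise ValueError("distance scores require at least 2 features")
    x = fm.values if scale == "none" else _minmax_columns(fm.values)
    dist = squareform(pdist(x.T, metric="euclidean"))
    return dist.sum(axis=1) / (m - 1)


@dataclass
class MRMDScoreTable:
    """Per-feature relevance, distance, combined score, and 1-based rank."""

    feature_names: list[str]
    mr: np.ndarray
    md: np.ndarray
    score: np.ndarray
    rank: np.ndarray  # rank[j] = position of feature j (1 = best)
    order: np.ndarray = field(repr=False)  # column indices best-first

    @property
    def ordered_names(self) -> list[str]:
        return [self.feature_names[j] for j in self.order]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.feature_names,
                "MR": self.mr,
                "MD": self.md,
                "score": self.score,
                "rank": self.rank,
            }
        )


def mrmd_rank(fm: FeatureMatrix, scale: str = "minmax") -> MRMDScoreTable:
    """Score and rank all features; stable descending sort on MR + MD."""
    mr = mr_scores(fm)
    md = md_scores(fm, scale=scale)
    score = mr + md
    order = np.argsort(-score, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(1, len(order) + 1)
    return MRMDScoreTable(list(fm.feature_names), mr, md, score, rank, order)


@dataclass
class SelectionResult:
    """Accuracy curve over candidate subset sizes and the chosen subset."""

    sizes: list[int]
    accuracies: list[float]
    chosen_features: list[str]
    chosen_size: int
    chosen_accuracy: float


def incremental_select(
    fm_train: FeatureMatrix,
    table: MRMDScoreTable,
    folds: int = 10,
    step: int = 1,
    seed: int = 0,
    trees: int = 100,
) -> SelectionResult:
    """Forward selection along the MRMD ranking.

    Evaluates subsets of the top ``step``, ``2*step``, ... features (the
    full set is always included) by stratified ``folds``-fold
    cross-validated accuracy of a seeded random forest, and returns the
    smallest subset achieving the maximum accuracy.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if fm_train.labels is None:
        raise ValueError("selection requires a labeled matrix")
    class_sizes = np.bincount(fm_train.labels, minlength=2)
    if class_sizes.min() < folds:
        raise ValueError(
            f"smallest class ({class_sizes.min()}) is smaller than folds ({folds})"
        )
    if set(table.feature_names) != set(fm_train.feature_names):
        raise ValueError("score table does not rank exactly the matrix's features")

    ranked = table.ordered_names
    m = len(ranked)
    sizes = list(range(step, m + 1, step))
    if sizes[-1] != m:
        sizes.append(m)

    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accuracies = []
    for size in sizes:
        sub = fm_train.select(ranked[:size])
        clf = RandomForestClassifier(n_estimators=trees, random_state=seed, n_jobs=1)
        acc = cross_val_score(
            clf, sub.values, sub.labels, cv=cv, scoring="accuracy"
        ).mean()
        accuracies.append(float(acc))

    best = int(np.argmax(accuracies))  # argmax takes the first => smallest size
    return SelectionResult(
        sizes=sizes,
        accuracies=accuracies,
        chosen_features=ranked[: sizes[best]],
        chosen_size=sizes[best],
        chosen_accuracy=accuracies[best],
    )
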