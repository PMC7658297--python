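"""Random-forest training and the binary evaluation suite.

The classifier is a vote-based random forest: the positive-class score
of a sample is the fraction of trees voting positive, and the decision
threshold for confusion counts is 0.5 (ties go positive).  Metrics are
computed from the confusion counts:

    Sn  = TP / (TP + FN)                      (sensitivity / recall)
    Sp  = TN / (TN + FP)                      (specificity)
    Acc = (TP + TN) / (TP + FN + TN + FP)
    F   = 2 TP / (2 TP + FN + FP)             (F1)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FN)(TP+FP)(TN+FP)(TN+FN))

with the convention that a metric whose denominator vanishes is 0.  AUC
is the trapezoidal area under the ROC curve (Sn against 1 - Sp over all
vote-fraction thresholds); tied scores cross the threshold together,
which matches the rank-statistic form with ties at half weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .sequence_io import FeatureMatrix


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN

    @classmethod
    def from_predictions(cls, labels: np.ndarray, predictions: np.ndarray) -> "ConfusionCounts":
        labels = np.asarray(labels, dtype=int)
        predictions = np.asarray(predictions, dtype=int)
        return cls(
            TP=int(((labels == 1) & (predictions == 1)).sum()),
            FP=int(((labels == 0) & (predictions == 1)).sum()),
            FN=int(((labels == 1) & (predictions == 0)).sum()),
            TN=int(((labels == 0) & (predictions == 0)).sum()),
        )

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP, self.FP + other.FP, self.FN + other.FN, self.TN + other.TN
        )


@dataclass
class MetricsReport:
    Sn: float
    Sp: float
    Acc: float
    F: float
    MCC: float
    AUC: Optional[float] = None
    roc_points: Optional[np.ndarray] = None  # ordered (1 - Sp, Sn) pairs

    def as_dict(self) -> dict[str, float]:
        d = {"Sn": self.Sn, "Sp": self.Sp, "Acc": self.Acc, "F": self.F, "MCC": self.MCC}
        if self.AUC is not None:
            d["AUC"] = self.AUC
        return d


def _safe_div(num: float, den: float) -> float:
    return num / den if den != 0 else 0.0


def metrics_from_confusion(cc: ConfusionCounts) -> MetricsReport:
    """Sn/Sp/Acc/F/MCC from raw counts (degenerate denominators give 0)."""
    tp, fp, fn, tn = cc.TP, cc.FP, cc.FN, cc.TN
    mcc_den = (tp + fn) * (tp + fp) * (tn + fp) * (tn + fn)
    return MetricsReport(
        Sn=_safe_div(tp, tp + fn),
        Sp=_safe_div(tn, tn + fp),
        Acc=_safe_div(tp + tn, cc.total),
        F=_safe_div(2 * tp, 2 * tp + fn + fp),
        MCC=_safe_div(tp * tn - fp * fn, float(np.sqrt(mcc_den))) if mcc_den else 0.0,
    )


def roc_points(labels: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """ROC polyline as ordered (1 - Sp, Sn) pairs from (0,0) to (1,1)."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    order = np.argsort(-scores, kind="stable")
    pts = [(0.0, 0.0)]
    tp = fp = 0
    prev_score = None
    for i in order:
        if prev_score is not None and scores[i] != prev_score:
            pts.append((fp / n_neg, tp / n_pos))
        tp += labels[i] == 1
        fp += labels[i] == 0
        prev_score = scores[i]
    pts.append((1.0, 1.0))
    return np.array(pts)


def auc_score(labels: np.ndarray, scores: np.ndarray) -> float:
    """Trapezoidal area under the ROC curve."""
    pts = roc_points(labels, scores)
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


@dataclass
class ModelBundle:
    """A trained forest plus the feature columns it expects."""

    model: RandomForestClassifier
    feature_names: list[str]
    trees: int
    seed: int
    metadata: dict = field(default_factory=dict)

    def _matrix(self, fm: FeatureMatrix) -> np.ndarray:
        missing = [f for f in self.feature_names if f not in set(fm.feature_names)]
        if missing:
            raise ValueError(
                f"matrix lacks {len(missing)} features the model expects, "
                f"e.g. {missing[:5]}"
            )
        return fm.select(self.feature_names).values

    def vote_fractions(self, fm: FeatureMatrix) -> np.ndarray:
        """Fraction of trees voting positive, per sample."""
        x = self._matrix(fm)
        votes = np.stack([tree.predict(x) for tree in self.model.estimators_])
        return votes.mean(axis=0)

    def predict(self, fm: FeatureMatrix, threshold: float = 0.5) -> np.ndarray:
        return (self.vote_fractions(fm) >= threshold).astype(int)


def train_forest(
    fm: FeatureMatrix,
    subset: Optional[Sequence[str]] = None,
    trees: int = 100,
    seed: int = 0,
) -> ModelBundle:
    """Fit a seeded random forest on the given feature subset.

    Defaults follow common forest practice: unlimited depth, sqrt(M)
    candidate features per split.  ``subset=None`` uses all columns.
    """
    if fm.labels is None:
        raise ValueError("training requires a labeled matrix")
    if len(np.unique(fm.labels)) < 2:
        raise ValueError("training requires both classes present")
    names = list(subset) if subset is not None else list(fm.feature_names)
    sub = fm.select(names)  # raises on unknown names
    model = RandomForestClassifier(n_estimators=trees, random_state=seed, n_jobs=1)
    model.fit(sub.values, sub.labels)
    return ModelBundle(model=model, feature_names=names, trees=trees, seed=seed)


def evaluate(
    model: ModelBundle, fm_test: FeatureMatrix, threshold: float = 0.5
) -> tuple[ConfusionCounts, MetricsReport]:
    """Confusion counts and the full metric suite on a labeled test matrix."""
    if fm_test.labels is None:
        raise ValueError("evaluation requires a labeled test matrix")
    scores = model.vote_fractions(fm_test)
    preds = (scores >= threshold).astype(int)
    cc = ConfusionCounts.from_predictions(fm_test.labels, preds)
    report = metrics_from_confusion(cc)
    n_pos, n_neg = cc.TP + cc.FN, cc.TN + cc.FP
    if n_pos and n_neg:
        report.roc_points = roc_points(fm_test.labels, scores)
        report.AUC = float(np.trapezoid(report.roc_points[:, 1], report.roc_points[:, 0]))
        # internal consistency: Acc decomposes over class-conditional rates
        assert abs(report.Acc - (report.Sn * n_pos + report.Sp * n_neg) / cc.total) < 1e-12
    return cc, report


@dataclass
class CrossValResult:
    fold_reports: list[MetricsReport]
    mean_report: MetricsReport
    pooled_confusion: ConfusionCounts


def cross_validate(
    fm: FeatureMatrix,
    subset: Optional[Sequence[str]] = None,
    folds: int = 10,
    trees: int = 100,
    seed: int = 0,
) -> CrossValResult:
    """Stratified k-fold evaluation; per-fold metrics, their mean, and the
    pooled confusion over all held-out folds."""
    if fm.labels is None:
        raise ValueError("cross-validation requires a labeled matrix")
    class_sizes = np.bincount(fm.labels, minlength=2)
    if class_sizes.min() < folds:
        raise ValueError(
            f"smallest class ({class_sizes.min()}) is smaller than folds ({folds})"
        )
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    reports: list[MetricsReport] = []
    pooled = ConfusionCounts(0, 0, 0, 0)
    for train_idx, test_idx in cv.split(fm.values, fm.labels):
        bundle = train_forest(fm.take(train_idx), subset, trees=trees, seed=seed)
        cc, rep = evaluate(bundle, fm.take(test_idx))
        reports.append(rep)
        pooled = pooled + cc
    mean = MetricsReport(
        Sn=float(np.mean([r.Sn for r in reports])),
        Sp=float(np.mean([r.Sp for r in reports])),
        Acc=float(np.mean([r.Acc for r in reports])),
        F=float(np.mean([r.F for r in reports])),
        MCC=float(np.mean([r.MCC for r in reports])),
        AUC=float(np.mean([r.AUC for r in reports if r.AUC is not None]))
        if any(r.AUC is not None for r in reports)
        else None,
    )
    return CrossValResult(reports, mean, pooled)


def group_feature_means(
    fm: FeatureMatrix, features: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Class-conditional feature means and their signed difference.

    One row per feature with columns ``mean_pos``, ``mean_neg`` and
    ``difference`` (positive minus negative), sortable by difference —
    the group-content comparison used to ask which descriptor features
    (e.g. hydrophobic-class triads) are enriched in the positive class.
    """
    if fm.labels is None:
        raise ValueError("group means require a labeled matrix")
    pos = fm.labels == 1
    neg = fm.labels == 0
    if not pos.any() or not neg.any():
        raise ValueError("group means require both classes present")
    sub = fm if features is None else fm.select(list(features))
    mean_pos = sub.values[pos].mean(axis=0)
    mean_neg = sub.values[neg].mean(axis=0)
    return pd.DataFrame(
        {
            "feature": sub.feature_names,
            "mean_pos": mean_pos,
            "mean_neg": mean_neg,
            "difference": mean_pos - mean_neg,
        }
    ).set_index("feature")
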