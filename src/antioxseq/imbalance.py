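"""Class rebalancing for labeled feature matrices.

Two samplers are provided, both applied to training data only:

* SMOTE oversampling — grows the minority class by synthetic points
  interpolated uniformly between a minority sample and one of its k
  nearest minority neighbours (Euclidean metric on the raw feature
  values, which are already frequency-scaled).
* Random undersampling — seeded uniform subsampling of the majority
  class without replacement.

Original rows always survive unchanged; synthetic rows are flagged in
their sample ids.  All randomness flows from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .sequence_io import FeatureMatrix


@dataclass(frozen=True)
class ResampleConfig:
    """Parameters of a rebalancing run.

    ``target_ratio`` is the minority:majority ratio after resampling
    (1.0 = fully balanced).  ``k_neighbors`` only applies to SMOTE.
    """

    method: str = "smote"
    k_neighbors: int = 5
    target_ratio: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("smote", "random_under"):
            raise ValueError(f"method must be 'smote' or 'random_under', got {self.method!r}")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if not 0 < self.target_ratio <= 1:
            raise ValueError("target_ratio must be in (0, 1]")


def _class_split(fm: FeatureMatrix) -> tuple[np.ndarray, np.ndarray, int, int]:
    if fm.labels is None:
        raise ValueError("resampling requires a labeled matrix")
    pos = np.flatnonzero(fm.labels == 1)
    neg = np.flatnonzero(fm.labels == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("resampling requires both classes present")
    if len(pos) <= len(neg):
        return pos, neg, 1, 0  # minority idx, majority idx, labels
    return neg, pos, 0, 1


def smote_oversample(fm: FeatureMatrix, cfg: ResampleConfig) -> FeatureMatrix:
    """Grow the minority class to ``target_ratio`` of the majority.

    Each synthetic row is x_i + u * (x_nn - x_i) with u ~ Uniform(0, 1)
    and x_nn one of the k nearest minority neighbours of x_i, so every
    synthetic coordinate lies between the two parents' coordinates.
    """
    min_idx, maj_idx, *_ = _class_split(fm)
    n_min, n_maj = len(min_idx), len(maj_idx)
    if n_min <= cfg.k_neighbors:
        raise ValueError(
            f"minority class of size {n_min} needs k_neighbors < {n_min} "
            f"(got {cfg.k_neighbors}); use a smaller k"
        )
    target = int(round(cfg.target_ratio * n_maj))
    n_new = target - n_min
    if n_new < 0:
        raise ValueError(
            f"minority class ({n_min}) already exceeds target size {target}"
        )
    if n_new == 0:
        return fm.take(range(fm.n_samples))

    x_min = fm.values[min_idx]
    nn = NearestNeighbors(n_neighbors=cfg.k_neighbors + 1).fit(x_min)
    # column 0 is the point itself
    neighbours = nn.kneighbors(x_min, return_distance=False)[:, 1:]

    rng = np.random.default_rng(cfg.seed)
    parents = rng.integers(0, n_min, size=n_new)
    picks = rng.integers(0, cfg.k_neighbors, size=n_new)
    u = rng.random(size=n_new)
    base = x_min[parents]
    partner = x_min[neighbours[parents, picks]]
    synthetic = base + u[:, None] * (partner - base)

    min_label = int(fm.labels[min_idx[0]])
    new_ids = [
        f"{fm.sample_ids[min_idx[p]]}__smote{j}" for j, p in enumerate(parents)
    ]
    return FeatureMatrix(
        list(fm.sample_ids) + new_ids,
        list(fm.feature_names),
        np.vstack([fm.values, synthetic]),
        np.concatenate([fm.labels, np.full(n_new, min_label, dtype=int)]),
    )


def random_undersample(fm: FeatureMatrix, cfg: ResampleConfig) -> FeatureMatrix:
    """Subsample the majority class without replacement to ``target_ratio``."""
    min_idx, maj_idx, *_ = _class_split(fm)
    n_min, n_maj = len(min_idx), len(maj_idx)
    target = int(round(n_min / cfg.target_ratio))
    if target > n_maj:
        raise ValueError(
            f"target majority size {target} exceeds majority class size {n_maj}"
        )
    rng = np.random.default_rng(cfg.seed)
    keep_maj = rng.choice(maj_idx, size=target, replace=False)
    keep = np.sort(np.concatenate([min_idx, keep_maj]))  # original row order
    return fm.take(keep)


def resample(fm: FeatureMatrix, cfg: ResampleConfig) -> FeatureMatrix:
    """Dispatch on ``cfg.method``."""
    if cfg.method == "smote":
        return smote_oversample(fm, cfg)
    return random_undersample(fm, cfg)
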