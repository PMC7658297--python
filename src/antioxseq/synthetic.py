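"""Planted-signal synthetic protein datasets.

Sequences are drawn i.i.d. per residue.  Negatives follow a background
profile (uniform over the 20 standard residues by default).  Positives
up-weight the hydrophobic residues A, G, V, I, L, F, P — conjoint-triad
classes 1 and 2 — by a multiplicative enrichment factor, which plants a
compositional signal visible to both the gapped-pair and triad
descriptors.  By default every positive shares the same enriched
profile; ``heterogeneity`` > 0 instead draws a per-sequence signal
strength

    s_i = 1 + (enrichment - 1) * g_i,     g_i ~ Gamma(1/h^2, h^2)

(g_i has mean 1 and coefficient of variation h), turning the positive
class into a mixture of strong and near-background sequences for
harder, more protein-family-like benchmarks.  ``enrichment=1`` is an
exact null: both classes share the background.

This is a deliberate simplification of real protein statistics — no
motifs, no ordering structure, no homology — so results on it speak to
the pipeline's mechanics, not to real antioxidant proteins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .sequence_io import STANDARD_AA, ProteinRecord, SequenceDataset

#: Hydrophobic residues (conjoint-triad classes 1 and 2).
HYDROPHOBIC = "AGVILFP"
_HYDRO_MASK = np.array([aa in HYDROPHOBIC for aa in STANDARD_AA])
_AA_ARRAY = np.array(list(STANDARD_AA))


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    """Parameters of the planted-signal generator."""

    n_pos: int
    n_neg: int
    length_range: tuple[int, int] = (50, 300)
    enrichment: float = 3.0
    background: Optional[Sequence[float]] = None
    heterogeneity: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("class sizes must be non-negative")
        lo, hi = self.length_range
        if lo < 5 or hi < lo:
            raise ValueError("length_range must satisfy 5 <= min <= max")
        if self.enrichment < 1:
            raise ValueError("enrichment must be >= 1")
        if self.heterogeneity < 0:
            raise ValueError("heterogeneity must be >= 0")
        if self.background is not None:
            bg = np.asarray(self.background, dtype=float)
            if bg.shape != (20,) or (bg <= 0).any():
                raise ValueError("background must be 20 positive frequencies")


def _background(spec: SyntheticDatasetSpec) -> np.ndarray:
    if spec.background is None:
        return np.full(20, 1 / 20)
    bg = np.asarray(spec.background, dtype=float)
    return bg / bg.sum()


def generate(spec: SyntheticDatasetSpec) -> SequenceDataset:
    """Draw the dataset; byte-identical for identical spec and seed."""
    rng = np.random.default_rng(spec.seed)
    bg = _background(spec)
    lo, hi = spec.length_range
    records = []

    def draw(profile: np.ndarray, rid: str, label: int) -> ProteinRecord:
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(_AA_ARRAY[rng.choice(20, size=length, p=profile)])
        return ProteinRecord(rid, seq, label)

    width = max(4, len(str(max(spec.n_pos, spec.n_neg))))
    for i in range(spec.n_pos):
        if spec.enrichment == 1 or spec.heterogeneity == 0:
            s = spec.enrichment
        else:
            shape = 1 / spec.heterogeneity**2
            s = 1 + (spec.enrichment - 1) * rng.gamma(shape, 1 / shape)
        profile = np.where(_HYDRO_MASK, bg * s, bg)
        profile = profile / profile.sum()
        records.append(draw(profile, f"pos{i + 1:0{width}d}", 1))
    for i in range(spec.n_neg):
        records.append(draw(bg, f"neg{i + 1:0{width}d}", 0))
    return SequenceDataset(records)


def benchmark_shape_dataset(
    seed: int, enrichment: float = 3.0, length_range: tuple[int, int] = (50, 300)
) -> tuple[SequenceDataset, SequenceDataset]:
    """Convenience preset mirroring the curated benchmark's shape.

    Generates 253 positives and 1552 negatives and designates a fixed
    split: 200 positives + 1500 negatives for training, the remaining
    53 positives + 52 negatives as the independent test set (disjoint
    ids by construction).
    """
    ds = generate(
        SyntheticDatasetSpec(
            n_pos=253, n_neg=1552, length_range=length_range, enrichment=enrichment, seed=seed
        )
    )
    pos = [r for r in ds if r.label == 1]
    neg = [r for r in ds if r.label == 0]
    train = SequenceDataset(pos[:200] + neg[:1500])
    test = SequenceDataset(pos[200:] + neg[1500:])
    return train, test
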