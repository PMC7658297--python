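"""CKSAAP and conjoint-triad (CT) sequence descriptors.

CKSAAP — composition of k-spaced amino-acid pairs — is the frequency of
each ordered residue pair (a, b) separated by exactly ``gap`` intervening
residues: f(a,b) = n(a,b) / (N - gap - 1), where N is the sequence length
and N - gap - 1 is the number of gapped windows (N - 4 at the default
gap of 3).  One gap value yields 20 x 20 = 400 features that sum to 1.

The conjoint-triad descriptor collapses the 20 amino acids into 7
physicochemical classes (dipole and side-chain volume):

    1 {A,G,V}  2 {I,L,F,P}  3 {Y,M,T,S}  4 {H,N,Q,W}  5 {R,K}  6 {D,E}  7 {C}

counts all 7^3 = 343 class triads over the N - 2 consecutive 3-residue
windows, and normalizes the count vector v as d_i = (v_i - min v) / max v
(the descriptor's published normalization; a range-denominator variant is
available via ``norm="range"``).

The combined feature set is the 400-column CKSAAP block followed by the
343-column CT block: 743 features.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import SequenceValidationError
from .sequence_io import STANDARD_AA, FeatureMatrix, SequenceDataset

#: Conjoint-triad classes, 1-based, in their canonical order.
CT_CLASSES: dict[int, str] = {
    1: "AGV",
    2: "ILFP",
    3: "YMTS",
    4: "HNQW",
    5: "RK",
    6: "DE",
    7: "C",
}

#: Amino acid -> CT class (1..7).
CT_CLASS_OF: dict[str, int] = {aa: c for c, members in CT_CLASSES.items() for aa in members}

_AA_CODE = np.full(128, -1, dtype=np.int64)
for _i, _a in enumerate(STANDARD_AA):
    _AA_CODE[ord(_a)] = _i

_CT_CODE = np.full(128, -1, dtype=np.int64)
for _a, _c in CT_CLASS_OF.items():
    _CT_CODE[ord(_a)] = _c - 1  # 0-based internally


def _encode(seq: str) -> np.ndarray:
    """Sequence -> integer codes 0..19 in canonical alphabet order."""
    raw = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    codes = _AA_CODE[np.minimum(raw, 127)]
    if (codes < 0).any():
        bad = seq[int(np.argmax(codes < 0))]
        raise SequenceValidationError(f"non-standard letter {bad!r} in sequence")
    return codes


def cksaap_feature_names(gap: int = 3) -> list[str]:
    return [f"{a}{b}.gap{gap}" for a in STANDARD_AA for b in STANDARD_AA]


def ct_feature_names() -> list[str]:
    return [f"ct{c1}{c2}{c3}" for c1 in range(1, 8) for c2 in range(1, 8) for c3 in range(1, 8)]


def cksaap_vector(seq: str, gap: int = 3) -> np.ndarray:
    """400-dimensional k-spaced pair frequencies for a single gap value.

    Index of pair (a, b) is ``20 * rank(a) + rank(b)`` in canonical
    alphabet order.  Requires at least one window: len(seq) > gap + 1.
    """
    if gap < 0:
        raise ValueError("gap must be non-negative")
    codes = _encode(seq)
    n = codes.size
    windows = n - gap - 1
    if windows < 1:
        raise ValueError(
            f"sequence of length {n} too short for gap {gap} "
            f"(needs length >= {gap + 2})"
        )
    pair_idx = codes[:windows] * 20 + codes[gap + 1 :]
    counts = np.bincount(pair_idx, minlength=400)
    return counts / windows


@dataclass(frozen=True)
class CTVector:
    """Raw triad counts alongside the normalized 343-vector."""

    raw_counts: np.ndarray
    values: np.ndarray


def ct_vector(seq: str, norm: str = "max") -> CTVector:
    """Conjoint-triad descriptor of a sequence of length >= 3.

    Triad (c1, c2, c3) maps to index (c1-1)*49 + (c2-1)*7 + (c3-1) with
    classes in canonical order.  ``norm="max"`` divides by max(v) (the
    published form); ``norm="range"`` divides by max(v) - min(v).
    """
    if norm not in ("max", "range"):
        raise ValueError(f"norm must be 'max' or 'range', got {norm!r}")
    classes = _CT_CODE[np.minimum(np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8), 127)]
    if (classes < 0).any():
        bad = seq[int(np.argmax(classes < 0))]
        raise SequenceValidationError(f"non-standard letter {bad!r} in sequence")
    n = classes.size
    if n < 3:
        raise ValueError(f"sequence of length {n} too short for triads (needs >= 3)")
    tri_idx = classes[:-2] * 49 + classes[1:-1] * 7 + classes[2:]
    v = np.bincount(tri_idx, minlength=343).astype(float)
    vmin, vmax = v.min(), v.max()
    denom = vmax if norm == "max" else vmax - vmin
    values = (v - vmin) / denom if denom > 0 else np.zeros_like(v)
    return CTVector(raw_counts=v, values=values)


def min_sequence_length(gaps: Sequence[int], features: Sequence[str]) -> int:
    """Shortest sequence both requested descriptors are defined for."""
    need = 1
    if "cksaap" in features:
        need = max(need, max(gaps) + 2)
    if "ct" in features:
        need = max(need, 3)
    return need


def extract_features(
    ds: SequenceDataset,
    gap: int | Sequence[int] = 3,
    features: Sequence[str] = ("cksaap", "ct"),
    ct_norm: str = "max",
) -> FeatureMatrix:
    """Combined descriptor matrix: CKSAAP block(s) first, then the CT block.

    With the defaults this is the 743-column feature set (400 pair
    frequencies at gap 3, then 343 normalized triad values).  ``gap`` may
    be a sequence of gap values, producing one 400-column block per gap
    in the given order.  Sequences failing a descriptor precondition
    raise an error naming the record.
    """
    unknown = set(features) - {"cksaap", "ct"}
    if unknown:
        raise ValueError(f"unknown feature families: {sorted(unknown)}")
    if not features:
        raise ValueError("at least one feature family required")
    gaps = [gap] if isinstance(gap, int) else list(gap)

    names: list[str] = []
    if "cksaap" in features:
        for g in gaps:
            names.extend(cksaap_feature_names(g))
    if "ct" in features:
        names.extend(ct_feature_names())

    rows = np.empty((len(ds), len(names)), dtype=float)
    for i, rec in enumerate(ds):
        parts = []
        try:
            if "cksaap" in features:
                parts.extend(cksaap_vector(rec.sequence, g) for g in gaps)
            if "ct" in features:
                parts.append(ct_vector(rec.sequence, norm=ct_norm).values)
        except (ValueError, SequenceValidationError) as exc:
            raise type(exc)(f"record {rec.id!r}: {exc}") from exc
        rows[i] = np.concatenate(parts)
    return FeatureMatrix(ds.ids, names, rows, ds.labels())
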