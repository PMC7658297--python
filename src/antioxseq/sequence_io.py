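"""Labeled protein-sequence and feature-matrix I/O.

Sequences travel as FASTA (read through Biopython); feature matrices as
CSV with a mandatory header row, the sample identifier in the first
column and, when the matrix is labeled, a trailing ``label`` column
(1 = positive / antioxidant, 0 = negative).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import FastaParseError, FeatureCSVError, SequenceValidationError

logger = logging.getLogger(__name__)

#: Canonical ordering of the 20 standard amino acids.  Every descriptor
#: index in the package is defined relative to this string.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
_STANDARD_SET = frozenset(STANDARD_AA)


@dataclass(frozen=True)
class ProteinRecord:
    """One identified amino-acid sequence with an optional binary label."""

    id: str
    sequence: str
    label: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")

    def invalid_letters(self) -> str:
        """Letters in the sequence outside the standard alphabet, in order."""
        seen = []
        for ch in self.sequence:
            if ch not in _STANDARD_SET and ch not in seen:
                seen.append(ch)
        return "".join(seen)


@dataclass
class SequenceDataset:
    """Ordered collection of :class:`ProteinRecord` with unique ids."""

    records: list[ProteinRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate record ids: {', '.join(dupes)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)

    def __getitem__(self, idx: int) -> ProteinRecord:
        return self.records[idx]

    @property
    def n_positive(self) -> int:
        return sum(1 for r in self.records if r.label == 1)

    @property
    def n_negative(self) -> int:
        return sum(1 for r in self.records if r.label == 0)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def labels(self) -> Optional[np.ndarray]:
        """Label vector, or None if any record is unlabeled."""
        if any(r.label is None for r in self.records):
            return None
        return np.array([r.label for r in self.records], dtype=int)

    def concat(self, other: "SequenceDataset") -> "SequenceDataset":
        return SequenceDataset(self.records + other.records)


def read_fasta(path: str | Path, label: Optional[int] = None) -> SequenceDataset:
    """Read a FASTA file into a :class:`SequenceDataset`.

    Sequences are uppercased.  ``label``, if given, is applied to every
    record.  Raises :class:`FastaParseError` on files that are not FASTA
    and on duplicate ids; an empty file yields an empty dataset with a
    logged warning.
    """
    path = Path(path)
    text_seen = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                text_seen = True
                if not line.startswith(">"):
                    raise FastaParseError(
                        f"{path}: line {lineno} is not a FASTA header "
                        f"(expected '>', got {line.strip()[:30]!r})"
                    )
                break
    if not text_seen:
        logger.warning("FASTA file %s is empty", path)
        return SequenceDataset([])

    records = []
    seen_ids: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen_ids:
            raise FastaParseError(f"{path}: duplicate record id {entry.id!r}")
        seen_ids.add(entry.id)
        records.append(ProteinRecord(entry.id, str(entry.seq).upper(), label))
    return SequenceDataset(records)


def write_fasta(ds: SequenceDataset, path: str | Path) -> None:
    """Write sequences as single-line-per-record FASTA (deterministic bytes)."""
    with open(path, "w") as fh:
        for rec in ds:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def read_label_table(path: str | Path) -> dict[str, int]:
    """Read an ``id,label`` CSV into a mapping."""
    df = pd.read_csv(path, dtype={0: str})
    if df.shape[1] < 2:
        raise FeatureCSVError(f"{path}: label table needs id and label columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1].astype(int)))


def write_label_table(ds: SequenceDataset, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id,label\n")
        for rec in ds:
            if rec.label is None:
                raise ValueError(f"record {rec.id!r} has no label")
            fh.write(f"{rec.id},{rec.label}\n")


def apply_labels(ds: SequenceDataset, labels: dict[str, int]) -> SequenceDataset:
    """Attach labels from a mapping; every record must be covered."""
    missing = [r.id for r in ds if r.id not in labels]
    if missing:
        raise ValueError(f"no label for records: {', '.join(missing[:5])}")
    return SequenceDataset([replace(r, label=labels[r.id]) for r in ds])


def validate_sequences(ds: SequenceDataset, policy: str = "drop") -> SequenceDataset:
    """Remove or reject records with residues outside the standard alphabet.

    Ambiguity codes (B, X, Z), rare letters (J, O, U), gaps and stop
    symbols are all treated identically: the pair/triad descriptors are
    undefined for them.  ``policy="drop"`` removes offending records and
    logs the count; ``policy="error"`` raises on the first one.  Empty
    sequences are invalid under both policies.
    """
    if policy not in ("drop", "error"):
        raise ValueError(f"policy must be 'drop' or 'error', got {policy!r}")
    kept = []
    dropped = 0
    for rec in ds:
        bad = rec.invalid_letters()
        ok = not bad and len(rec.sequence) > 0
        if ok:
            kept.append(rec)
        elif policy == "error":
            detail = f"non-standard letter(s) {bad!r}" if bad else "empty sequence"
            raise SequenceValidationError(f"record {rec.id!r}: {detail}")
        else:
            dropped += 1
    if dropped:
        logger.warning("validate_sequences: dropped %d of %d records", dropped, len(ds))
    return SequenceDataset(kept)


def stratified_split(
    ds: SequenceDataset, n_test_pos: int, n_test_neg: int, seed: int
) -> tuple[SequenceDataset, SequenceDataset]:
    """Seeded stratified train/test split with exact per-class test counts."""
    labels = ds.labels()
    if labels is None:
        raise ValueError("stratified split requires a fully labeled dataset")
    rng = np.random.default_rng(seed)
    test_idx: set[int] = set()
    for cls, n_test in ((1, n_test_pos), (0, n_test_neg)):
        cls_idx = np.flatnonzero(labels == cls)
        if n_test > len(cls_idx):
            raise ValueError(
                f"requested {n_test} test samples from class {cls} of size {len(cls_idx)}"
            )
        test_idx.update(rng.choice(cls_idx, size=n_test, replace=False).tolist())
    train = SequenceDataset([r for i, r in enumerate(ds) if i not in test_idx])
    test = SequenceDataset([r for i, r in enumerate(ds) if i in test_idx])
    return train, test


# ---------------------------------------------------------------------------
# Feature matrices


@dataclass
class FeatureMatrix:
    """Samples x named features with an optional aligned binary label vector."""

    sample_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n, m = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.feature_names) != m:
            raise ValueError(f"{len(self.feature_names)} feature names for {m} columns")
        if len(set(self.feature_names)) != m:
            raise ValueError("feature names must be unique")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample ids must be unique")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (n,):
                raise ValueError("labels must align with rows")
            if not np.isin(self.labels, (0, 1)).all():
                raise ValueError("labels must be binary 0/1")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureMatrix):
            return NotImplemented
        if self.sample_ids != other.sample_ids or self.feature_names != other.feature_names:
            return False
        if (self.labels is None) != (other.labels is None):
            return False
        if self.labels is not None and not np.array_equal(self.labels, other.labels):
            return False
        return np.array_equal(self.values, other.values)

    def select(self, feature_names: Sequence[str]) -> "FeatureMatrix":
        """Column subset (in the requested order), preserving ids and labels."""
        pos = {name: j for j, name in enumerate(self.feature_names)}
        missing = [f for f in feature_names if f not in pos]
        if missing:
            raise KeyError(f"unknown features: {', '.join(missing[:10])}")
        cols = [pos[f] for f in feature_names]
        return FeatureMatrix(
            list(self.sample_ids),
            list(feature_names),
            self.values[:, cols].copy(),
            None if self.labels is None else self.labels.copy(),
        )

    def take(self, row_idx: Iterable[int]) -> "FeatureMatrix":
        """Row subset by integer index."""
        idx = np.asarray(list(row_idx), dtype=int)
        return FeatureMatrix(
            [self.sample_ids[i] for i in idx],
            list(self.feature_names),
            self.values[idx].copy(),
            None if self.labels is None else self.labels[idx].copy(),
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "sample_id", self.sample_ids)
        if self.labels is not None:
            df["label"] = self.labels
        return df


def write_feature_csv(fm: FeatureMatrix, path: str | Path) -> None:
    """Serialize a feature matrix; floats round-trip exactly (repr form)."""
    fm.to_dataframe().to_csv(path, index=False)


def read_feature_csv(path: str | Path, require_labels: bool = False) -> FeatureMatrix:
    """Read a feature-matrix CSV written by :func:`write_feature_csv`.

    Lines starting with ``#`` (provenance stamps) are ignored.  Raises
    :class:`FeatureCSVError` with the row/column of the first non-numeric
    feature cell, and when ``require_labels`` is set but no ``label``
    column is present.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, comment="#", skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise FeatureCSVError(f"{path}: file has no header row")
    if df.columns[0] != "sample_id":
        raise FeatureCSVError(f"{path}: first column must be 'sample_id'")
    has_labels = df.columns[-1] == "label"
    if require_labels and not has_labels:
        raise FeatureCSVError(f"{path}: labeled matrix required but no 'label' column")
    feat_cols = list(df.columns[1 : -1 if has_labels else len(df.columns)])
    n = len(df)
    values = np.empty((n, len(feat_cols)), dtype=float)
    for j, col in enumerate(feat_cols):
        try:
            values[:, j] = df[col].astype(float)
        except ValueError:
            for i, cell in enumerate(df[col]):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise FeatureCSVError(
                        f"{path}: non-numeric value {cell!r} at data row {i + 1}, "
                        f"column {col!r}"
                    )
            raise
    labels = None
    if has_labels:
        try:
            labels = df["label"].astype(int).to_numpy() if n else np.empty(0, dtype=int)
        except ValueError:
            raise FeatureCSVError(f"{path}: label column must contain integers 0/1")
    return FeatureMatrix(list(df["sample_id"]) if n else [], feat_cols, values, labels)
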