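import numpy as np
import pytest

from antioxseq.sequence_io import FeatureMatrix, ProteinRecord, SequenceDataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_dataset():
    return SequenceDataset(
        [
            ProteinRecord("a", "ACDEFGHIKL", 1),
            ProteinRecord("b", "AAAAAAGGGG", 1),
            ProteinRecord("c", "MNPQRSTVWY", 0),
            ProteinRecord("d", "CCCCCDDDDD", 0),
        ]
    )


def make_matrix(values, labels=None, prefix="f"):
    values = np.asarray(values, dtype=float)
    return FeatureMatrix(
        [f"s{i}" for i in range(values.shape[0])],
        [f"{prefix}{j}" for j in range(values.shape[1])],
        values,
        labels,
    )


@pytest.fixture
def imbalanced_matrix(rng):
    """200 positives / 1500 negatives, 10 numeric features."""
    n_pos, n_neg = 200, 1500
    values = rng.random((n_pos + n_neg, 10))
    labels = np.array([1] * n_pos + [0] * n_neg)
    return make_matrix(values, labels)
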