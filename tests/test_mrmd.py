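"""MRMD ranking: relevance/distance scores, oracle equivalence, selection."""

import numpy as np
import pytest

from antioxseq.mrmd import (
    incremental_select,
    md_scores,
    mr_scores,
    mrmd_rank,
    pearson_correlation,
)

from conftest import make_matrix


def naive_mrmd(values, labels):
    """Independent double-loop reimplementation of the score table.

    Textbook Pearson formula and explicit pairwise Euclidean loops on
    min-max-scaled columns, written without vectorization so it shares
    no code path with the implementation under test.
    """
    n, m = values.shape
    scaled = np.empty_like(values)
    for j in range(m):
        col = values[:, j]
        span = col.max() - col.min()
        scaled[:, j] = 0.0 if span == 0 else (col - col.min()) / span
    mr = np.empty(m)
    for j in range(m):
        x, y = values[:, j], labels.astype(float)
        num = sum((a - x.mean()) * (b - y.mean()) for a, b in zip(x, y))
        den = np.sqrt(sum((a - x.mean()) ** 2 for a in x)) * np.sqrt(
            sum((b - y.mean()) ** 2 for b in y)
        )
        mr[j] = abs(num / den) if den > 0 else 0.0
    md = np.zeros(m)
    for i in range(m):
        for k in range(m):
            if k != i:
                md[i] += np.sqrt(sum((scaled[s, i] - scaled[s, k]) ** 2 for s in range(n)))
        md[i] /= m - 1
    return mr, md, mr + md


class TestPearson:
    def test_self_correlation_is_one(self):
        assert pearson_correlation([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_exact_anticorrelation(self):
        assert pearson_correlation([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        x = np.array([1.0, 2, 3, 4])
        y = np.array([1.0, 3, 2, 4])
        num = ((x - x.mean()) * (y - y.mean())).sum()
        den = np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        assert pearson_correlation(x, y) == pytest.approx(num / den, abs=1e-15)

    def test_zero_variance_returns_zero_with_warning(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            assert pearson_correlation([1, 1, 1], [1, 2, 3]) == 0.0

    def test_length_mismatch_and_short_input_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            pearson_correlation([1], [1])


class TestScores:
    def test_mr_feature_equal_to_labels(self):
        labels = np.array([1, 0, 1, 0, 1])
        fm = make_matrix(labels[:, None].astype(float), labels)
        assert mr_scores(fm)[0] == pytest.approx(1.0)

    def test_mr_inverted_label_feature(self):
        labels = np.array([1, 0, 1, 0])
        fm = make_matrix((1 - labels)[:, None].astype(float), labels)
        assert mr_scores(fm)[0] == pytest.approx(1.0)

    def test_mr_constant_feature_is_zero(self):
        labels = np.array([1, 0, 1, 0])
        fm = make_matrix(np.ones((4, 1)), labels)
        assert mr_scores(fm)[0] == 0.0

    def test_mr_requires_labels(self, rng):
        fm = make_matrix(rng.random((5, 2)))
        with pytest.raises(ValueError, match="labeled"):
            mr_scores(fm)

    def test_md_hand_euclidean(self):
        # columns (0,0) and (3,4): distance 5
        fm = make_matrix(np.array([[0.0, 3.0], [0.0, 4.0]]))
        np.testing.assert_allclose(md_scores(fm, scale="none"), [5.0, 5.0])

    def test_md_duplicate_columns_contribute_zero(self):
        fm = make_matrix(np.array([[1.0, 1.0], [2.0, 2.0], [0.5, 0.5]]))
        np.testing.assert_allclose(md_scores(fm, scale="none"), [0.0, 0.0])

    def test_md_single_feature_rejected(self):
        fm = make_matrix(np.array([[1.0], [2.0]]))
        with pytest.raises(ValueError, match="at least 2"):
            md_scores(fm)


class TestRanking:
    def test_score_is_sum_and_rank_permutation(self, rng):
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        fm = make_matrix(rng.random((30, 8)), labels)
        table = mrmd_rank(fm)
        np.testing.assert_allclose(table.score, table.mr + table.md)
        assert sorted(table.rank) == list(range(1, 9))
        ordered = table.score[table.order]
        assert all(ordered[i] >= ordered[i + 1] for i in range(len(ordered) - 1))

    def test_tied_identical_columns_keep_original_order(self):
        labels = np.array([1, 0, 1, 0, 1, 0])
        col = np.array([0.9, 0.1, 0.8, 0.2, 0.7, 0.3])
        fm = make_matrix(np.column_stack([col, col]), labels)
        table = mrmd_rank(fm)
        assert list(table.order) == [0, 1]

    def test_row_permutation_invariance(self, rng):
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        values = rng.random((40, 6))
        fm = make_matrix(values, labels)
        perm = rng.permutation(40)
        fm_perm = make_matrix(values[perm], labels[perm])
        np.testing.assert_allclose(mrmd_rank(fm).score, mrmd_rank(fm_perm).score, atol=1e-12)

    def test_mr_invariant_to_increasing_affine_transform(self, rng):
        labels = rng.integers(0, 2, 25)
        labels[:2] = [0, 1]
        values = rng.random((25, 3))
        fm = make_matrix(values, labels)
        fm2 = make_matrix(values * 7.5 + 3.0, labels)
        np.testing.assert_allclose(mr_scores(fm), mr_scores(fm2), atol=1e-12)

    def test_oracle_equivalence_random_matrices(self, rng):
        for _ in range(5):
            labels = rng.integers(0, 2, 10)
            labels[:2] = [0, 1]
            fm = make_matrix(rng.random((10, 8)), labels)
            table = mrmd_rank(fm)
            mr, md, score = naive_mrmd(fm.values, fm.labels)
            np.testing.assert_allclose(table.mr, mr, atol=1e-12)
            np.testing.assert_allclose(table.md, md, atol=1e-12)
            np.testing.assert_allclose(table.score, score, atol=1e-12)


class TestIncrementalSelect:
    def _planted(self, rng, n=80, n_noise=8, n_signal=2, effect=2.0):
        labels = np.array([1, 0] * (n // 2))
        noise = rng.random((n, n_noise))
        signal = rng.random((n, n_signal)) + effect * labels[:, None]
        return make_matrix(np.hstack([signal, noise]), labels)

    def test_smallest_size_at_max_accuracy_wins(self, rng):
        fm = self._planted(rng)
        table = mrmd_rank(fm)
        sel = incremental_select(fm, table, folds=4, step=1, seed=0, trees=20)
        assert sel.chosen_accuracy == max(sel.accuracies)
        first_max = sel.sizes[int(np.argmax(sel.accuracies))]
        assert sel.chosen_size == first_max

    def test_full_set_always_evaluated(self, rng):
        fm = self._planted(rng)
        sel = incremental_select(fm, mrmd_rank(fm), folds=4, step=3, seed=0, trees=20)
        assert sel.sizes[-1] == fm.n_features
        assert sel.chosen_accuracy >= sel.accuracies[-1]

    def test_single_feature_matrix_unsupported_by_md(self, rng):
        # ranking needs >= 2 features; selection of a 2-feature table can pick 1
        fm = self._planted(rng, n_noise=1, n_signal=1)
        sel = incremental_select(fm, mrmd_rank(fm), folds=4, step=1, seed=0, trees=20)
        assert sel.chosen_size in (1, 2)

    def test_parameter_validation(self, rng):
        fm = self._planted(rng)
        table = mrmd_rank(fm)
        with pytest.raises(ValueError, match="step"):
            incremental_select(fm, table, step=0)
        with pytest.raises(ValueError, match="folds"):
            incremental_select(fm, table, folds=1)
        with pytest.raises(ValueError, match="smaller than folds"):
            incremental_select(fm, table, folds=200)

    def test_planted_features_recovered(self, rng):
        # per-feature signal weak enough that no single feature suffices,
        # so the accuracy curve keeps rising until the planted set is in
        labels = np.array([1, 0] * 60)
        signal = 0.8 * labels[:, None] + rng.normal(size=(120, 3))
        noise = rng.normal(size=(120, 20))
        fm = make_matrix(np.hstack([signal, noise]), labels)
        table = mrmd_rank(fm)
        sel = incremental_select(fm, table, folds=5, step=1, seed=1, trees=30)
        chosen = set(sel.chosen_features)
        assert len(chosen & {"f0", "f1", "f2"}) >= 2
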