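import numpy as np
import pytest

from credfilter.features import FeatureMatrix, FeatureSpec
from credfilter.selection import (
    FoldAssignment,
    ModelConfig,
    default_fold_count,
    encode_labels,
    evaluate_roc,
    make_folds,
    model_search,
    rfe_select,
)


def _matrix(X, family="LEXICON"):
    n, d = X.shape
    return FeatureMatrix(
        row_ids=[f"r{i}" for i in range(n)],
        specs=[FeatureSpec(family, f"f{j}") for j in range(d)],
        values=X,
    )


def auc_pair_counting(y, p):
    """O(n^2) oracle: P(random positive outranks random negative), ties 1/2."""
    pos = p[y == 1]
    neg = p[y == 0]
    wins = sum((pp > nn) + 0.5 * (pp == nn) for pp in pos for nn in neg)
    return wins / (len(pos) * len(neg))


class TestFolds:
    @pytest.mark.parametrize("n,k", [(600, 10), (120, 3), (250, 5), (49, 3), (10000, 10)])
    def test_default_fold_count_clamped(self, n, k):
        assert default_fold_count(n) == k

    def test_stratification_balances_minority(self):
        labels = ["positive"] * 10 + ["negative"] * 40
        folds = make_folds(labels, k=5, seed=0)
        y = encode_labels(labels)
        for f in range(5):
            assert np.sum(y[folds.fold_of == f] == 1) == 2

    def test_fold_sizes_within_one_per_class(self):
        rng = np.random.default_rng(3)
        y = (rng.random(173) < 0.3).astype(int)
        folds = make_folds(y, k=4, seed=1)
        for cls in (0, 1):
            sizes = [np.sum((folds.fold_of == f) & (y == cls)) for f in range(4)]
            assert max(sizes) - min(sizes) <= 1

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            make_folds(["positive"] * 20, k=3)

    def test_seeded_determinism(self):
        labels = ["positive", "negative"] * 30
        f1 = make_folds(labels, k=4, seed=9)
        f2 = make_folds(labels, k=4, seed=9)
        assert np.array_equal(f1.fold_of, f2.fold_of)


class TestRFE:
    def test_default_target_is_30_percent(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(100, 40))
        y = (rng.random(100) < 0.5).astype(int)
        selected = rfe_select(_matrix(X), y)
        assert len(selected) == 30

    def test_identity_when_target_equals_columns(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 5))
        y = (rng.random(30) < 0.5).astype(int)
        m = _matrix(X)
        assert rfe_select(m, y, n_target=5) == m.specs

    def test_informative_column_retained_over_noise(self):
        # pure noise vs label +- small noise, n_target=1
        kept = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            y = (rng.random(80) < 0.5).astype(int)
            X = np.column_stack([rng.normal(size=80), y + 0.1 * rng.normal(size=80)])
            X = (X - X.mean(0)) / X.std(0)
            (spec,) = rfe_select(_matrix(X), y, n_target=1, seed=seed)
            kept += spec.name == "f1"
        assert kept == 5

    def test_nonpositive_target_rejected(self):
        X = np.zeros((10, 3))
        with pytest.raises(ValueError):
            rfe_select(_matrix(X), np.array([0, 1] * 5), n_target=0)


class TestModelSearch:
    def _folds(self, y, k=3, seed=0):
        return make_folds(y, k=k, seed=seed)

    def test_degenerate_grid_covers_every_sample_once(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 4))
        y = np.array([0, 1] * 30)
        folds = self._folds(y)
        config, oof, board = model_search(
            _matrix(X), y, folds, grids={"regularized-linear": [{"C": 1.0}]}
        )
        assert config.family == "regularized-linear"
        assert len(oof.p_positive) == 60
        assert not np.any(np.isnan(oof.p_positive))
        assert len(board) == 1
        assert set(oof.models) == set(range(folds.k))

    def test_separable_data_reaches_perfect_f1(self):
        rng = np.random.default_rng(2)
        y = np.array([0, 1] * 40)
        X = np.column_stack([y * 4.0 - 2.0 + 0.05 * rng.normal(size=80),
                             rng.normal(size=80)])
        folds = self._folds(y)
        _, _, board = model_search(
            _matrix(X), y, folds, grids={"regularized-linear": [{"C": 10.0}]}
        )
        assert board["mean_f1"].iloc[0] == pytest.approx(1.0)

    def test_same_seed_identical_results(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(90, 5))
        y = (rng.random(90) < 0.4).astype(int)
        folds = self._folds(y, seed=7)
        grids = {
            "regularized-linear": [{"C": 1.0}],
            "multilayer-perceptron": [{"hidden_layer_sizes": (8,), "max_iter": 200}],
        }
        c1, o1, _ = model_search(_matrix(X), y, folds, grids=grids, seed=5)
        c2, o2, _ = model_search(_matrix(X), y, folds, grids=grids, seed=5)
        assert c1 == c2
        assert np.array_equal(o1.p_positive, o2.p_positive)

    def test_empty_grid_rejected(self):
        X = np.zeros((10, 2))
        y = np.array([0, 1] * 5)
        with pytest.raises(ValueError, match="empty"):
            model_search(_matrix(X), y, self._folds(y, k=2), grids={})

    def test_mean_f1_matches_hand_computation(self):
        # 10-sample fixture, k=2: recompute the fold F1s from the OOF
        # probabilities with the textbook 2PR/(P+R) and compare
        rng = np.random.default_rng(8)
        X = rng.normal(size=(10, 2))
        y = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
        folds = make_folds(y, k=2, seed=0)
        _, oof, board = model_search(
            _matrix(X), y, folds, grids={"regularized-linear": [{"C": 1.0}]}
        )
        f1s = []
        for f in range(2):
            mask = folds.fold_of == f
            pred = (oof.p_positive[mask] >= 0.5).astype(int)
            truth = y[mask]
            tp = np.sum((pred == 1) & (truth == 1))
            fp = np.sum((pred == 1) & (truth == 0))
            fn = np.sum((pred == 0) & (truth == 1))
            precision = tp / (tp + fp) if tp + fp else 0.0
            recall = tp / (tp + fn) if tp + fn else 0.0
            f1s.append(2 * precision * recall / (precision + recall)
                       if precision + recall else 0.0)
        assert board["mean_f1"].iloc[0] == pytest.approx(np.mean(f1s))

    def test_tie_breaks_toward_simpler_family(self):
        # two identical linear configs under different family labels is not
        # constructible; instead check that with equal scores the first
        # (simpler) candidate is kept: duplicate grid points in one family
        rng = np.random.default_rng(6)
        X = rng.normal(size=(40, 3))
        y = np.array([0, 1] * 20)
        folds = self._folds(y)
        config, _, _ = model_search(
            _matrix(X), y, folds,
            grids={"regularized-linear": [{"C": 1.0}, {"C": 1.0 + 1e-15}]},
        )
        assert config.hp["C"] == 1.0


class TestROC:
    def test_perfect_ranking(self):
        y = np.array([0, 0, 1, 1])
        _, auc = evaluate_roc(np.array([0.1, 0.2, 0.8, 0.9]), y)
        assert auc == 1.0

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(10, 60))
            y = (rng.random(n) < 0.5).astype(int)
            if len(np.unique(y)) < 2:
                continue
            p = np.round(rng.random(n), 2)  # rounding forces ties
            _, auc = evaluate_roc(p, y)
            assert auc == pytest.approx(auc_pair_counting(y, p), abs=1e-12)

    def test_independent_scores_near_half(self):
        rng = np.random.default_rng(0)
        n = 2000
        y = (rng.random(n) < 0.5).astype(int)
        p = rng.random(n)
        _, auc = evaluate_roc(p, y)
        n1, n0 = y.sum(), n - y.sum()
        se = np.sqrt((n1 + n0 + 1) / (12 * n1 * n0))  # Mann-Whitney null SE
        assert abs(auc - 0.5) <= 3 * se

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            evaluate_roc(np.array([0.1, 0.2]), np.array([1, 1]))
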