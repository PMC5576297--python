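"""Balanced partitioning, base-predictor training, diversity selection, voting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pssmrt.ensemble import (
    BasePredictor,
    EnsembleModel,
    build_balanced_sets,
    diversity,
    load_model,
    manifest_hash,
    partition_negatives,
    save_model,
    select_predictors,
    train_base_predictors,
    vote_predict,
)


class TestPartition:
    def test_spec_sizes(self):
        part = partition_negatives(range(100), 30, seed=0)
        assert part.n == 3
        assert sorted(len(s) for s in part.subsets) == [33, 33, 34]

    def test_balanced_input_single_subset(self):
        part = partition_negatives(range(10), 10, seed=0)
        assert part.n == 1
        assert len(part.subsets[0]) == 10

    def test_determinism(self):
        a = partition_negatives(range(57), 13, seed=42)
        b = partition_negatives(range(57), 13, seed=42)
        assert a.subsets == b.subsets

    def test_zero_positives_rejected(self):
        with pytest.raises(ValueError):
            partition_negatives(range(10), 0, seed=0)

    @given(n_neg=st.integers(5, 300), n_pos=st.integers(1, 100), seed=st.integers(0, 5))
    @settings(max_examples=60, deadline=None)
    def test_cover_disjoint_size_bounds(self, n_neg, n_pos, seed):
        part = partition_negatives(range(n_neg), n_pos, seed)
        flat = [i for s in part.subsets for i in s]
        assert sorted(flat) == list(range(n_neg))  # cover, disjoint
        target = int(np.ceil(n_neg / part.n))
        assert all(abs(len(s) - target) <= 1 for s in part.subsets)


class TestBalancedSets:
    def test_construction(self):
        part = partition_negatives(range(100, 200), 30, seed=1)
        sets = build_balanced_sets(part, range(30))
        assert len(sets) == part.n
        for s in sets:
            assert sorted(set(s) & set(range(30))) == list(range(30))
        negs = sorted(i for s in sets for i in s if i >= 100)
        assert negs == list(range(100, 200))

    def test_id_collision_rejected(self):
        part = partition_negatives(range(10), 5, seed=0)
        with pytest.raises(ValueError, match="both positive and negative"):
            build_balanced_sets(part, [3, 100])


class TestDiversity:
    @pytest.mark.parametrize(
        "a,b,expected",
        [([1, 1, 0], [1, 1, 0], 0.0), ([1, 0, 1], [0, 1, 0], 1.0), ([1, 1, 0, 0], [1, 0, 1, 0], 0.5)],
    )
    def test_values(self, a, b, expected):
        assert diversity(a, b) == expected

    def test_symmetry_bounds(self, rng):
        a = rng.integers(0, 2, 50)
        b = rng.integers(0, 2, 50)
        d = diversity(a, b)
        assert 0 <= d <= 1
        assert d == diversity(b, a)
        assert (d == 0) == bool(np.array_equal(a, b))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            diversity([1, 0], [1])


class _FixedPredictor(BasePredictor):
    """Test double returning canned labels regardless of features."""

    def __init__(self, pid, labels):
        super().__init__(pid, "svm-rbf", "pssm-rt", 0, None, np.arange(len(labels)))
        self._labels = np.asarray(labels)

    def predict(self, X):
        return self._labels


def _pool(label_rows):
    return [_FixedPredictor(f"p{i}", row) for i, row in enumerate(label_rows)]


class TestSelection:
    VAL = {"pssm-rt": np.zeros((4, 1))}

    def test_complementary_selected_second(self):
        base = [1, 1, 0, 0]
        pool = _pool([base, base, [0, 0, 1, 1]])
        # seed chosen so that the random start is p0
        model = None
        for seed in range(20):
            m = select_predictors(pool, self.VAL, epsilon=0.01, seed=seed)
            if m.trace[0]["id"] == "p0":
                model = m
                break
        assert model is not None
        assert model.trace[1]["id"] == "p2"

    def test_identical_pool_selects_one(self):
        pool = _pool([[1, 0, 1, 0]] * 4)
        model = select_predictors(pool, self.VAL, epsilon=0.01, seed=0)
        assert len(model.predictors) == 1

    def test_trace_determinism(self):
        rng = np.random.default_rng(7)
        pool = _pool(rng.integers(0, 2, size=(6, 4)))
        m1 = select_predictors(pool, self.VAL, epsilon=0.05, seed=3)
        m2 = select_predictors(pool, self.VAL, epsilon=0.05, seed=3)
        assert m1.selected_ids == m2.selected_ids
        assert m1.trace == m2.trace

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            select_predictors([], self.VAL, epsilon=0.1, seed=0)

    def test_selected_diversity_meets_threshold(self):
        rng = np.random.default_rng(11)
        pool = _pool(rng.integers(0, 2, size=(10, 4)))
        model = select_predictors(pool, self.VAL, epsilon=0.3, seed=1)
        for step in model.trace[1:]:
            assert step["mean_diversity"] >= 0.3


class TestVote:
    def test_strict_majority(self):
        model = EnsembleModel(_pool([[1], [1], [0]]), 0.1, 0, [], 3)
        labels, scores = vote_predict(model, {"pssm-rt": np.zeros((1, 1))})
        assert labels[0] == 1
        assert scores[0] == pytest.approx(2 / 3)

    def test_tie_goes_positive(self):
        model = EnsembleModel(_pool([[1], [0]]), 0.1, 0, [], 3)
        labels, scores = vote_predict(model, {"pssm-rt": np.zeros((1, 1))})
        assert labels[0] == 1
        assert scores[0] == 0.5

    def test_unanimous_negative(self):
        model = EnsembleModel(_pool([[0], [0], [0]]), 0.1, 0, [], 3)
        labels, scores = vote_predict(model, {"pssm-rt": np.zeros((1, 1))})
        assert labels[0] == 0
        assert scores[0] == 0.0


class TestTraining:
    @pytest.fixture
    def tiny_data(self, rng):
        n, d = 60, 6
        X = rng.normal(size=(n, d))
        y = (X[:, 0] > 0).astype(int)
        features = {"pssm-rt": X, "sequence": X[:, :3], "physicochemical": X[:, 3:]}
        return features, y

    def test_predictor_count_six_per_set(self, tiny_data):
        features, y = tiny_data
        pool = train_base_predictors([np.arange(60)], features, y, seed=0)
        assert len(pool) == 6
        pool4 = train_base_predictors([np.arange(60)] * 4, features, y, seed=0)
        assert len(pool4) == 24

    def test_rf_determinism(self, tiny_data):
        features, y = tiny_data
        p1 = train_base_predictors([np.arange(60)], features, y, seed=5)
        p2 = train_base_predictors([np.arange(60)] * 1, features, y, seed=5)
        rf1 = next(p for p in p1 if p.algorithm == "random-forest")
        rf2 = next(p for p in p2 if p.algorithm == "random-forest")
        X = features[rf1.feature_block]
        assert np.array_equal(rf1.predict(X), rf2.predict(X))

    def test_single_class_set_rejected(self, tiny_data):
        features, y = tiny_data
        ids = np.flatnonzero(y == 1)
        with pytest.raises(ValueError, match="single class"):
            train_base_predictors([ids], features, y, seed=0)

    def test_persistence_round_trip(self, tiny_data, tmp_path):
        features, y = tiny_data
        pool = train_base_predictors([np.arange(60)], features, y, seed=0)
        model = select_predictors(pool, features, epsilon=0.0, seed=0, window_size=13)
        save_model(model, tmp_path / "m")
        loaded = load_model(tmp_path / "m")
        assert loaded.selected_ids == model.selected_ids
        l1, s1 = vote_predict(model, features)
        l2, s2 = vote_predict(loaded, features)
        assert np.array_equal(l1, l2) and np.array_equal(s1, s2)
        assert len(manifest_hash(tmp_path / "m")) == 64
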