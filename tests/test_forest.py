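"""Forest training, voting, determinism, and brute-force oracle equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import encoded_from_arrays

from sumohunt.dataset import NEGATIVE, POSITIVE
from sumohunt.forest import (
    DecisionTreeNode,
    ForestModel,
    default_mtry,
    predict,
    predict_batch,
    train_forest,
)
from sumohunt.errors import PredictionError, TrainingError

# ---------------------------------------------------------------------------
# Independent brute-force oracle: an exhaustive Gini tree written in plain
# Python loops, sharing only the documented tie-break contract (lowest
# feature index, then smallest threshold; leaf ties vote negative).


def _gini(labels):
    n = len(labels)
    p = sum(labels) / n
    return 1.0 - p * p - (1.0 - p) * (1.0 - p)


def _oracle_build(X, y, rows):
    labels = [y[i] for i in rows]
    if all(labels) or not any(labels):
        return ("leaf", sum(labels) > len(labels) - sum(labels))
    n = len(rows)
    parent = _gini(labels)
    best = None  # (gain, feature, threshold)
    for f in range(len(X[0])):
        values = sorted({X[i][f] for i in rows})
        for a, b in zip(values, values[1:]):
            thr = (a + b) / 2.0
            left = [i for i in rows if X[i][f] <= thr]
            right = [i for i in rows if X[i][f] > thr]
            gain = (
                parent
                - len(left) / n * _gini([y[i] for i in left])
                - len(right) / n * _gini([y[i] for i in right])
            )
            if gain > 1e-12 and (best is None or gain > best[0] + 1e-12):
                best = (gain, f, thr)
    if best is None:
        pos = sum(labels)
        return ("leaf", pos > len(labels) - pos)
    _, f, thr = best
    left = [i for i in rows if X[i][f] <= thr]
    right = [i for i in rows if X[i][f] > thr]
    return ("node", f, thr, _oracle_build(X, y, left), _oracle_build(X, y, right))


def oracle_predict(tree, x):
    while tree[0] == "node":
        _, f, thr, left, right = tree
        tree = left if x[f] <= thr else right
    return tree[1]


def exhaustive_tree_predictions(X, y, test_points):
    tree = _oracle_build([list(r) for r in X], list(y), list(range(len(y))))
    return [oracle_predict(tree, list(x)) for x in test_points]


binary_dataset = st.integers(min_value=2, max_value=12).flatmap(
    lambda n: st.tuples(
        st.lists(
            st.lists(st.integers(0, 1), min_size=3, max_size=3),
            min_size=n,
            max_size=n,
        ),
        st.lists(st.booleans(), min_size=n, max_size=n),
    )
)


class TestOracleEquivalence:
    def _assert_equivalent(self, X, y):
        data = encoded_from_arrays(X, y)
        model = train_forest(data, n_trees=1, mtry=3, seed=0, bootstrap=False)
        grid = [[a, b, c] for a in (0, 1) for b in (0, 1) for c in (0, 1)]
        ours = [predict(model, np.array(g, dtype=float)).label == POSITIVE for g in grid]
        oracle = exhaustive_tree_predictions(X, y, grid)
        assert ours == oracle

    def test_fixed_twelve_by_three(self):
        X = [
            [0, 0, 0], [0, 0, 1], [0, 1, 0], [0, 1, 1],
            [1, 0, 0], [1, 0, 1], [1, 1, 0], [1, 1, 1],
            [0, 0, 0], [1, 1, 0], [1, 0, 1], [0, 1, 1],
        ]
        y = [0, 0, 0, 1, 1, 1, 1, 1, 0, 1, 0, 1]
        self._assert_equivalent(X, y)

    @given(binary_dataset)
    @settings(max_examples=120, deadline=None, derandomize=True)
    def test_random_small_binary_datasets(self, data):
        X, y = data
        if all(y) or not any(y):
            return  # untrainable; the contract requires both classes
        self._assert_equivalent(X, y)


class TestVoting:
    def _leaf_forest(self, votes):
        trees = [
            DecisionTreeNode(counts=(0, 1) if v else (1, 0)) for v in votes
        ]
        return ForestModel(
            trees=trees, n_trees=len(trees), mtry=1, seed=0,
            feature_count=2, class_counts=(1, 1),
        )

    def test_unanimous_positive(self):
        pred = predict(self._leaf_forest([True] * 10), np.zeros(2))
        assert (pred.label, pred.vote_fraction) == (POSITIVE, 1.0)

    def test_exact_tie_is_negative(self):
        pred = predict(self._leaf_forest([True] * 5 + [False] * 5), np.zeros(2))
        assert (pred.label, pred.vote_fraction) == (NEGATIVE, 0.5)

    def test_vote_fraction_granularity(self):
        model = self._leaf_forest([True] * 3 + [False] * 7)
        pred = predict(model, np.zeros(2))
        assert pred.vote_fraction == pytest.approx(0.3)
        assert pred.label == NEGATIVE


class TestTraining:
    @pytest.fixture
    def separable(self):
        rng = np.random.default_rng(5)
        n = 40
        x0 = np.concatenate([rng.uniform(1, 3, n // 2), rng.uniform(-3, -1, n // 2)])
        X = np.column_stack([x0, rng.normal(size=n), rng.normal(size=n)])
        y = np.concatenate([np.ones(n // 2, bool), np.zeros(n // 2, bool)])
        return encoded_from_arrays(X, y)

    def test_default_is_ten_trees(self, separable):
        model = train_forest(separable, seed=0)
        assert model.n_trees == 10
        assert model.mtry == default_mtry(3)

    def test_separable_recovery(self, separable):
        model = train_forest(separable, seed=0)
        assert predict(model, np.array([2.0, 0.0, 0.0])).label == POSITIVE
        assert predict(model, np.array([-2.0, 0.0, 0.0])).label == NEGATIVE

    def test_seeded_determinism(self, separable):
        m1 = train_forest(separable, seed=11)
        m2 = train_forest(separable, seed=11)
        assert m1.to_json() == m2.to_json()
        probe = np.array([[0.5, 1.0, -1.0]])
        assert predict_batch(m1, probe)[1] == predict_batch(m2, probe)[1]

    def test_feature_permutation_invariance(self, separable):
        # With all features considered at every node (mtry = M), consistently
        # permuting feature columns permutes split indices but not predictions.
        perm = [2, 0, 1]
        permuted = encoded_from_arrays(separable.X[:, perm], separable.y)
        m = train_forest(separable, mtry=3, seed=3)
        mp = train_forest(permuted, mtry=3, seed=3)
        probes = np.random.default_rng(0).normal(size=(20, 3))
        assert np.array_equal(
            predict_batch(m, probes)[0], predict_batch(mp, probes[:, perm])[0]
        )

    def test_json_round_trip_predictions(self, separable):
        model = train_forest(separable, seed=2)
        back = ForestModel.from_json(model.to_json())
        probes = np.random.default_rng(1).normal(size=(25, 3))
        assert np.array_equal(predict_batch(model, probes)[1], predict_batch(back, probes)[1])

    def test_single_class_rejected(self):
        data = encoded_from_arrays([[0.0], [1.0]], [True, True])
        with pytest.raises(TrainingError):
            train_forest(data, seed=0)

    def test_mtry_out_of_range(self, separable):
        with pytest.raises(TrainingError):
            train_forest(separable, mtry=4, seed=0)

    def test_vector_length_mismatch(self, separable):
        model = train_forest(separable, seed=0)
        with pytest.raises(PredictionError):
            predict(model, np.zeros(5))

    def test_vote_fraction_lattice(self, separable):
        model = train_forest(separable, n_trees=7, seed=0)
        _, fracs = predict_batch(model, separable.X)
        lattice = {i / 7 for i in range(8)}
        assert set(np.round(fracs, 10)) <= {round(v, 10) for v in lattice}
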