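"""Random forest classifier: bagged, feature-randomized Gini trees.

Each of the ``n_trees`` trees is grown on a bootstrap sample of the training
instances (n draws with replacement).  At every node a uniform random subset
of ``mtry`` features is considered; the split maximizing Gini impurity
decrease is taken, with candidate thresholds at midpoints between
consecutive distinct sorted values.  Trees grow to purity (minimum leaf size
1, unlimited depth) unless no candidate split reduces impurity.  The forest
predicts by majority vote; an exact 50/50 tie is resolved to the negative
class, a deliberately conservative rule for a site predictor.

Randomness contract: a single master seed spawns one independent stream per
tree, so each tree's bootstrap and feature draws are independent of every
other tree's but fully reproducible.

Deterministic tie-breaks (part of the model contract, relied on by the
brute-force oracle tests): among equally good splits the lowest feature
index wins, then the smallest threshold; a leaf with equal class counts
predicts negative.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .dataset import NEGATIVE, POSITIVE
from .encoding import EncodedDataset, FeatureVector
from .errors import PredictionError, TrainingError

_SERIAL_VERSION = 1
_EPS = 1e-12


@dataclass
class DecisionTreeNode:
    """Internal node (feature, threshold, children) or leaf (label, counts).

    Internal nodes route ``value <= threshold`` left and ``> threshold``
    right.  Leaves carry the training class counts ``(n_negative,
    n_positive)`` they were grown from.
    """

    feature: Optional[int] = None
    threshold: Optional[float] = None
    left: Optional["DecisionTreeNode"] = None
    right: Optional["DecisionTreeNode"] = None
    counts: Optional[tuple[int, int]] = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def label(self) -> bool:
        """Leaf vote: True = positive; equal counts vote negative."""
        neg, pos = self.counts
        return pos > neg

    def predict_one(self, x: np.ndarray) -> bool:
        node = self
        while not node.is_leaf:
            node = node.left if x[node.feature] <= node.threshold else node.right
        return node.label

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"counts": list(self.counts)}
        return {
            "feature": self.feature,
            "threshold": self.threshold,
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "DecisionTreeNode":
        if "counts" in doc:
            return cls(counts=tuple(doc["counts"]))
        return cls(
            feature=doc["feature"],
            threshold=doc["threshold"],
            left=cls.from_dict(doc["left"]),
            right=cls.from_dict(doc["right"]),
        )


@dataclass(frozen=True)
class Prediction:
    """Forest vote for one instance."""

    label: str
    vote_fraction: float


@dataclass
class ForestModel:
    """A trained forest plus everything needed to reproduce it."""

    trees: list[DecisionTreeNode]
    n_trees: int
    mtry: int
    seed: int
    feature_count: int
    class_counts: tuple[int, int]
    feature_names: tuple[str, ...] = ()

    def to_json(self) -> str:
        doc = {
            "format_version": _SERIAL_VERSION,
            "n_trees": self.n_trees,
            "mtry": self.mtry,
            "seed": self.seed,
            "feature_count": self.feature_count,
            "class_counts": list(self.class_counts),
            "feature_names": list(self.feature_names),
            "trees": [t.to_dict() for t in self.trees],
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "ForestModel":
        doc = json.loads(text)
        if doc.get("format_version") != _SERIAL_VERSION:
            raise PredictionError(
                f"unsupported model format version {doc.get('format_version')!r}"
            )
        return cls(
            trees=[DecisionTreeNode.from_dict(t) for t in doc["trees"]],
            n_trees=doc["n_trees"],
            mtry=doc["mtry"],
            seed=doc["seed"],
            feature_count=doc["feature_count"],
            class_counts=tuple(doc["class_counts"]),
            feature_names=tuple(doc["feature_names"]),
        )


def default_mtry(feature_count: int) -> int:
    """``floor(log2(M)) + 1`` — the classic forest default for M features."""
    return int(math.floor(math.log2(feature_count))) + 1


def _gini_split_gain(col: np.ndarray, y: np.ndarray) -> tuple[float, float] | None:
    """Best (gain, threshold) for one feature column, or None if unsplittable.

    Vectorized scan over midpoints of consecutive distinct sorted values.
    Among equal gains the smallest threshold wins.
    """
    order = np.argsort(col, kind="stable")
    sv = col[order]
    sy = y[order]
    n = sv.shape[0]
    boundaries = np.nonzero(sv[:-1] < sv[1:])[0]  # split after index i
    if boundaries.size == 0:
        return None
    pos_cum = np.cumsum(sy)
    total_pos = pos_cum[-1]
    n_left = boundaries + 1
    n_right = n - n_left
    pos_left = pos_cum[boundaries]
    pos_right = total_pos - pos_left
    # Gini of a node with n_c instances, p_c positives: 1 - p^2 - (1-p)^2,
    # weighted child impurity = sum n_c/n * gini_c.
    def weighted(nc, pc):
        frac_pos = pc / nc
        return (nc / n) * (1.0 - frac_pos**2 - (1.0 - frac_pos) ** 2)

    parent_pos = total_pos / n
    parent_gini = 1.0 - parent_pos**2 - (1.0 - parent_pos) ** 2
    gain = parent_gini - weighted(n_left, pos_left) - weighted(n_right, pos_right)
    best = int(np.argmax(gain))  # first (= smallest threshold) among ties
    i = boundaries[best]
    threshold = (sv[i] + sv[i + 1]) / 2.0
    return float(gain[best]), float(threshold)


def _grow_tree(
    X: np.ndarray,
    y: np.ndarray,
    mtry: int,
    rng: Optional[np.random.Generator],
) -> DecisionTreeNode:
    """Recursively grow one tree.  ``rng=None`` means consider all features."""
    n, m = X.shape
    counts = (int(n - y.sum()), int(y.sum()))
    if counts[0] == 0 or counts[1] == 0:
        return DecisionTreeNode(counts=counts)
    if rng is None or mtry >= m:
        candidates = np.arange(m)
    else:
        candidates = np.sort(rng.choice(m, size=mtry, replace=False))
    best_gain, best_feature, best_threshold = _EPS, -1, 0.0
    for f in candidates:  # ascending: lowest feature index wins ties
        res = _gini_split_gain(X[:, f], y)
        if res is None:
            continue
        gain, threshold = res
        if gain > best_gain + _EPS:
            best_gain, best_feature, best_threshold = gain, int(f), threshold
    if best_feature < 0:
        return DecisionTreeNode(counts=counts)
    mask = X[:, best_feature] <= best_threshold
    return DecisionTreeNode(
        feature=best_feature,
        threshold=best_threshold,
        left=_grow_tree(X[mask], y[mask], mtry, rng),
        right=_grow_tree(X[~mask], y[~mask], mtry, rng),
    )


def train_forest(
    data: EncodedDataset,
    n_trees: int = 10,
    mtry: Optional[int] = None,
    seed: int = 0,
    bootstrap: bool = True,
) -> ForestModel:
    """Train a forest of ``n_trees`` randomized trees on ``data``.

    ``mtry=None`` selects the default ``floor(log2(M)) + 1``.  Setting
    ``bootstrap=False`` grows every tree on the full training set (with
    ``n_trees=1, mtry=M`` this reduces the forest to a single deterministic
    exhaustive Gini tree, the configuration used for oracle checks).
    """
    X, y = np.asarray(data.X, dtype=float), np.asarray(data.y, dtype=bool)
    n, m = X.shape
    if n < 2:
        raise TrainingError(f"need at least 2 instances, got {n}")
    if y.all() or not y.any():
        raise TrainingError("training data contains a single class")
    if n_trees < 1:
        raise TrainingError(f"n_trees must be >= 1, got {n_trees}")
    if mtry is None:
        mtry = default_mtry(m)
    if not 1 <= mtry <= m:
        raise TrainingError(f"mtry {mtry} out of range [1, {m}]")
    streams = np.random.SeedSequence(seed).spawn(n_trees)
    trees = []
    for k in range(n_trees):
        rng = np.random.default_rng(streams[k])
        if bootstrap:
            idx = rng.integers(0, n, size=n)
            Xk, yk = X[idx], y[idx]
        else:
            Xk, yk = X, y
        if yk.all() or not yk.any():
            # Degenerate bootstrap draw: a single-class tree is a bare leaf.
            trees.append(
                DecisionTreeNode(counts=(int(len(yk) - yk.sum()), int(yk.sum())))
            )
            continue
        trees.append(_grow_tree(Xk, yk, mtry, rng if mtry < m else rng))
    return ForestModel(
        trees=trees,
        n_trees=n_trees,
        mtry=mtry,
        seed=seed,
        feature_count=m,
        class_counts=(int(n - y.sum()), int(y.sum())),
        feature_names=data.feature_names,
    )


def vote_fractions(model: ForestModel, X: np.ndarray) -> np.ndarray:
    """Fraction of trees voting positive for each row of ``X``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.feature_count:
        raise PredictionError(
            f"vector length {X.shape[1]} != model feature count {model.feature_count}"
        )
    votes = np.zeros(X.shape[0])
    for tree in model.trees:
        votes += [tree.predict_one(row) for row in X]
    return votes / model.n_trees


def predict(model: ForestModel, vector) -> Prediction:
    """Majority-vote prediction for one instance.

    Positive iff strictly more than half of the trees vote positive; an
    exact tie is negative.
    """
    values = vector.values if isinstance(vector, FeatureVector) else vector
    frac = float(vote_fractions(model, np.asarray(values, dtype=float))[0])
    return Prediction(POSITIVE if frac > 0.5 else NEGATIVE, frac)


def predict_batch(model: ForestModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(labels as booleans, vote fractions) for a feature matrix."""
    fracs = vote_fractions(model, X)
    return fracs > 0.5, fracs
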