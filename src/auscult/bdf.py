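"""Best-discrepancy forest: CART ensemble bagged by systematic low-discrepancy
sampling with replacement.

Ordinary bagging draws each tree's training multiset uniformly at random, so bag
class proportions fluctuate. Here each bag walks the dataset (sorted by class, then
source id) with the golden-ratio Weyl increment theta*N, theta = (sqrt(5)-1)/2, from
a random start: index_j = ordering[floor(u + j*theta*N) mod N]. Because the Weyl
sequence is equidistributed, every bag's class distribution closely mirrors the whole
dataset while duplicates remain possible ("with replacement"). Plain random bagging
is retained as a switch for ablations.

Individual trees are standard CART (Gini, random feature subsets of size mtry,
grown to purity) via scikit-learn; the ensemble predicts by plurality vote with ties
broken toward the smallest class index in the fixed vocabulary.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.tree import DecisionTreeClassifier

from .vocab import CLASSES, CLASS_INDEX

GOLDEN_RATIO_CONJUGATE = (math.sqrt(5.0) - 1.0) / 2.0

_FORMAT_VERSION = 1


def systematic_bag(n_total: int, n_bag: int, ordering: np.ndarray,
                   seed: int | np.random.SeedSequence) -> np.ndarray:
    """Low-discrepancy bag of ``n_bag`` indices into a dataset of size ``n_total``."""
    if n_total < 1 or n_bag < 1:
        raise ValueError("dataset and bag sizes must be >= 1")
    ordering = np.asarray(ordering)
    if ordering.shape != (n_total,) or not np.array_equal(np.sort(ordering),
                                                          np.arange(n_total)):
        raise ValueError("ordering must be a permutation of range(n_total)")
    rng = np.random.default_rng(seed)
    u = rng.uniform(0.0, n_total)
    pos = np.floor(u + np.arange(n_bag, dtype=np.float64)
                   * (GOLDEN_RATIO_CONJUGATE * n_total)).astype(np.int64) % n_total
    return ordering[pos]


def random_bag(n_total: int, n_bag: int,
               seed: int | np.random.SeedSequence) -> np.ndarray:
    """Simple random sampling with replacement (the ordinary random-forest bag)."""
    rng = np.random.default_rng(seed)
    return rng.integers(0, n_total, size=n_bag)


def fit_tree(x: np.ndarray, y: np.ndarray, mtry: int | None = None,
             seed: int | None = 0) -> DecisionTreeClassifier:
    """One CART tree: Gini splits, ``mtry`` candidate features per split, pure leaves."""
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    if x.shape[1] == 0:
        raise ValueError("need at least one feature")
    if mtry is None:
        mtry = math.ceil(math.sqrt(x.shape[1]))
    rs = seed if seed is None else int(np.random.default_rng(seed).integers(2 ** 31))
    tree = DecisionTreeClassifier(criterion="gini", max_features=mtry,
                                  min_samples_leaf=1, random_state=rs)
    tree.fit(x, np.asarray(y))
    return tree


@dataclass
class Forest:
    """Trained ensemble; trees predict indices into the fixed vocabulary."""

    trees: list = field(default_factory=list)
    classes: tuple = CLASSES
    mtry: int = 8
    bagging: str = "bdf"

    def __post_init__(self) -> None:
        if self.bagging not in ("bdf", "random"):
            raise ValueError("bagging must be 'bdf' or 'random'")

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def save(self, path) -> None:
        joblib.dump({"version": _FORMAT_VERSION, "forest": self}, path)

    @classmethod
    def load(cls, path) -> "Forest":
        blob = joblib.load(path)
        if blob.get("version") != _FORMAT_VERSION:
            raise ValueError("unsupported forest file version")
        return blob["forest"]


def class_ordering(y_idx: np.ndarray, source_ids=None) -> np.ndarray:
    """Dataset ordering for systematic strides: sort by class, then source id (stable).

    Walking this ordering with an equidistributed stride visits every class in
    proportion to its frequency, which is what keeps bag distributions close to the
    dataset distribution.
    """
    y_idx = np.asarray(y_idx)
    if source_ids is None:
        source_ids = np.arange(y_idx.size)
    return np.lexsort((np.asarray(source_ids), y_idx))


def fit_forest(x: np.ndarray, y, n_trees: int = 500, mtry: int | None = None,
               bagging: str = "bdf", bag_fraction: float = 1.0,
               source_ids=None, seed: int = 0) -> Forest:
    """Train the forest on 64-dim feature vectors.

    ``bag_fraction`` scales the bag size n relative to N (default 1.0, standard
    bagging size). ``bagging='random'`` switches to ordinary bootstrap bags.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    if not 0 < bag_fraction <= 1.0:
        raise ValueError("bag_fraction must be in (0, 1]")
    x = np.asarray(x, dtype=np.float64)
    y_idx = np.asarray([CLASS_INDEX[l] if isinstance(l, str) else int(l) for l in y])
    n = x.shape[0]
    if np.unique(y_idx).size < len(CLASSES):
        warnings.warn(f"training data covers {np.unique(y_idx).size}/{len(CLASSES)} "
                      "classes", stacklevel=2)
    if mtry is None:
        mtry = math.ceil(math.sqrt(x.shape[1]))
    ordering = class_ordering(y_idx, source_ids)
    n_bag = max(1, int(round(bag_fraction * n)))
    root = np.random.SeedSequence(seed)
    trees = []
    for child in root.spawn(n_trees):
        bag_seed, tree_seed = child.spawn(2)
        if bagging == "bdf":
            bag = systematic_bag(n, n_bag, ordering, bag_seed)
        elif bagging == "random":
            bag = random_bag(n, n_bag, bag_seed)
        else:
            raise ValueError("bagging must be 'bdf' or 'random'")
        tree = DecisionTreeClassifier(
            criterion="gini", max_features=mtry, min_samples_leaf=1,
            random_state=int(tree_seed.generate_state(1)[0] % 2 ** 31))
        tree.fit(x[bag], y_idx[bag])
        trees.append(tree)
    return Forest(trees=trees, mtry=mtry, bagging=bagging)


def vote_counts(forest: Forest, x: np.ndarray) -> np.ndarray:
    """Per-class vote counts, shape (n_samples, n_classes)."""
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    if x.shape[1] != forest.trees[0].n_features_in_:
        raise ValueError(f"expected {forest.trees[0].n_features_in_}-dim features")
    counts = np.zeros((x.shape[0], len(forest.classes)), dtype=np.int64)
    rows = np.arange(x.shape[0])
    for tree in forest.trees:
        pred = tree.predict(x)  # trees are trained on vocabulary indices
        counts[rows, np.asarray(pred, dtype=np.int64)] += 1
    return counts


def predict(forest: Forest, x: np.ndarray):
    """Plurality-vote label(s); ties go to the smallest vocabulary index.

    Returns ``(label, counts)`` for a single feature vector, or
    ``(labels, counts)`` arrays for a batch.
    """
    x = np.asarray(x, dtype=np.float64)
    single = x.ndim == 1
    counts = vote_counts(forest, x)
    winners = counts.argmax(axis=1)  # argmax takes the first maximum: smallest index
    labels = np.asarray([forest.classes[i] for i in winners])
    if single:
        return labels[0], counts[0]
    return labels, counts
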