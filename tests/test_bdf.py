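"""Systematic bagging, CART trees, forest voting."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from auscult.bdf import (
    Forest, class_ordering, fit_forest, fit_tree, predict, random_bag,
    systematic_bag, vote_counts,
)
from auscult.vocab import CLASSES


def blobs(n_per_class, dim=64, sep=6.0, seed=0, labels=("AS", "MS")):
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for i, lab in enumerate(labels):
        center = np.zeros(dim)
        center[i] = sep
        xs.append(center + rng.standard_normal((n_per_class, dim)))
        ys.extend([lab] * n_per_class)
    return np.concatenate(xs), np.array(ys)


class TestSystematicBag:
    def test_single_element_dataset(self):
        bag = systematic_bag(1, 3, np.array([0]), seed=0)
        assert np.array_equal(bag, [0, 0, 0])

    def test_class_proportions_preserved_on_sorted_data(self):
        # brute-force frequency count: 5 class-A then 5 class-B, huge bag
        bag = systematic_bag(10, 1000, np.arange(10), seed=1)
        frac_a = np.mean(bag < 5)
        assert abs(frac_a - 0.5) <= 0.02

    def test_deterministic_given_seed(self):
        a = systematic_bag(100, 100, np.arange(100), seed=9)
        b = systematic_bag(100, 100, np.arange(100), seed=9)
        assert np.array_equal(a, b)

    def test_invalid_permutation_rejected(self):
        with pytest.raises(ValueError, match="permutation"):
            systematic_bag(4, 4, np.array([0, 1, 1, 3]), seed=0)

    @given(st.integers(2, 200), st.integers(1, 300), st.integers(0, 2 ** 31 - 1))
    def test_bag_is_valid_multiset(self, n_total, n_bag, seed):
        bag = systematic_bag(n_total, n_bag, np.arange(n_total), seed=seed)
        assert bag.shape == (n_bag,)
        assert bag.min() >= 0 and bag.max() < n_total


class TestFitTree:
    def test_single_class_bag_gives_constant_predictor(self):
        x = np.random.default_rng(0).standard_normal((5, 4))
        tree = fit_tree(x, np.zeros(5, dtype=int))
        assert tree.get_depth() == 0
        assert (tree.predict(x) == 0).all()

    def test_two_points_split_perfectly(self):
        x = np.array([[0.0], [1.0]])
        tree = fit_tree(x, np.array([0, 1]), mtry=1)
        assert (tree.predict(x) == [0, 1]).all()

    def test_xor_learned_exactly_with_depth_two(self):
        # exhaustive check: no single axis split separates XOR, so depth >= 2
        x = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
        y = np.array([0, 1, 1, 0])
        tree = fit_tree(x, y, mtry=2, seed=0)
        assert (tree.predict(x) == y).all()
        assert tree.get_depth() >= 2

    def test_zero_features_rejected(self):
        with pytest.raises(ValueError):
            fit_tree(np.empty((3, 0)), np.zeros(3))


class TestForest:
    def test_single_tree_forest_equals_its_tree(self):
        x, y = blobs(20, dim=4, seed=2)
        forest = fit_forest(x, y, n_trees=1, seed=3)
        labels, _ = predict(forest, x)
        tree_pred = forest.trees[0].predict(x)
        assert np.array_equal([CLASSES[int(i)] for i in tree_pred], labels)

    def test_well_separated_blobs_classified_accurately(self):
        x, y = blobs(200, dim=64, sep=6.0, seed=4)
        tr = np.r_[0:160, 200:360]
        te = np.r_[160:200, 360:400]
        forest = fit_forest(x[tr], y[tr], n_trees=50, seed=5)
        labels, _ = predict(forest, x[te])
        assert np.mean(labels == y[te]) >= 0.95

    def test_bag_class_proportions_within_five_points(self):
        rng = np.random.default_rng(6)
        y = np.array(["AS"] * 60 + ["MS"] * 30 + ["MR"] * 10)
        y_idx = np.array([CLASSES.index(c) for c in y])
        ordering = class_ordering(y_idx)
        true_props = np.bincount(y_idx, minlength=len(CLASSES)) / y.size
        max_dev = 0.0
        for t in range(500):
            bag = systematic_bag(y.size, y.size, ordering,
                                 seed=np.random.SeedSequence(entropy=6, spawn_key=(t,)))
            props = np.bincount(y_idx[bag], minlength=len(CLASSES)) / y.size
            max_dev = max(max_dev, np.abs(props - true_props).max())
        assert max_dev <= 0.05

    def test_systematic_bags_lower_variance_than_random(self):
        y_idx = np.array([6] * 60 + [8] * 30 + [7] * 10)  # AS/MS/MR vocab indices
        ordering = class_ordering(y_idx)

        def prop_variance(bag_fn):
            props = []
            for t in range(500):
                seed = np.random.SeedSequence(entropy=11, spawn_key=(t,))
                bag = bag_fn(seed)
                props.append(np.bincount(y_idx[bag], minlength=len(CLASSES)) / y_idx.size)
            return np.var(np.asarray(props), axis=0).sum()

        var_sys = prop_variance(lambda s: systematic_bag(100, 100, ordering, s))
        var_rand = prop_variance(lambda s: random_bag(100, 100, s))
        assert var_sys <= var_rand

    def test_forest_not_worse_than_single_tree_across_seeds(self):
        wins = []
        for seed in range(10):
            x, y = blobs(40, dim=8, sep=2.0, seed=seed)
            rng = np.random.default_rng(seed)
            idx = rng.permutation(x.shape[0])
            tr, te = idx[:60], idx[60:]
            forest = fit_forest(x[tr], y[tr], n_trees=25, seed=seed)
            labels, _ = predict(forest, x[te])
            forest_acc = np.mean(labels == y[te])
            tree = fit_tree(x[tr], [CLASSES.index(c) for c in y[tr]], seed=seed)
            tree_acc = np.mean([CLASSES[int(i)] for i in tree.predict(x[te])] == y[te])
            wins.append(forest_acc >= tree_acc)
        assert np.mean(wins) >= 0.8  # ensembling does not hurt on this geometry

    def test_margin_stability_when_adding_trees(self):
        x, y = blobs(30, dim=8, seed=7)
        big = fit_forest(x, y, n_trees=40, seed=8)
        small = Forest(trees=big.trees[:30], mtry=big.mtry)
        counts_small = vote_counts(small, x)
        added = 10
        top2 = np.sort(counts_small, axis=1)[:, -2:]
        margin = top2[:, 1] - top2[:, 0]
        stable = margin > added
        labels_small = counts_small.argmax(axis=1)
        labels_big = vote_counts(big, x).argmax(axis=1)
        assert np.array_equal(labels_small[stable], labels_big[stable])

    def test_tie_breaks_toward_smallest_vocabulary_index(self):
        x = np.array([[0.0], [1.0]])
        t1 = fit_tree(x, np.array([CLASSES.index("MS")] * 2), mtry=1)  # always MS
        t2 = fit_tree(x, np.array([CLASSES.index("AS")] * 2), mtry=1)  # always AS
        forest = Forest(trees=[t1, t2], mtry=1)
        label, counts = predict(forest, np.array([0.5]))
        assert label == "AS"  # AS precedes MS in the vocabulary
        assert counts[CLASSES.index("AS")] == counts[CLASSES.index("MS")] == 1

    def test_dimension_mismatch_rejected(self):
        x, y = blobs(10, dim=8, seed=9)
        forest = fit_forest(x, y, n_trees=2, seed=0)
        with pytest.raises(ValueError, match="features"):
            predict(forest, np.zeros(5))

    def test_invalid_configs_rejected(self):
        x, y = blobs(5, dim=4, seed=0)
        with pytest.raises(ValueError):
            fit_forest(x, y, n_trees=0)
        with pytest.raises(ValueError):
            fit_forest(x, y, n_trees=1, bag_fraction=0.0)
        with pytest.raises(ValueError):
            fit_forest(x, y, n_trees=1, bagging="bogus")

    def test_save_load_roundtrip(self, tmp_path):
        x, y = blobs(10, dim=4, seed=1)
        forest = fit_forest(x, y, n_trees=3, seed=2)
        forest.save(tmp_path / "f.joblib")
        back = Forest.load(tmp_path / "f.joblib")
        assert np.array_equal(predict(back, x)[0], predict(forest, x)[0])
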