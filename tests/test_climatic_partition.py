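"""CART growth, CV pruning, leaf assignment, forest check, sensitivity."""

import numpy as np
import pandas as pd
import pytest
from sklearn.tree import DecisionTreeClassifier

from landrefugia import cart
from landrefugia import climatic_partition as cp
from landrefugia import synthetic_world as sw


def make_cells(X: np.ndarray, y: np.ndarray, var_names=None) -> pd.DataFrame:
    var_names = var_names or [f"bio{i + 1}" for i in range(X.shape[1])]
    table = pd.DataFrame(X, columns=var_names)
    table.insert(0, "cell_id", np.arange(len(X)))
    table["landcover"] = y
    return table


class TestFitTree:
    def test_perfect_1d_separation_single_split_at_class_gap(self):
        x = np.concatenate([np.linspace(0, 1, 30), np.linspace(2, 3, 30)])
        y = np.array(["a"] * 30 + ["b"] * 30)
        tree = cart.fit_tree(x.reshape(-1, 1), y, min_split=10)
        assert tree.n_leaves == 2
        root = tree.nodes[0]
        assert 1.0 < root.threshold < 2.0
        assert (tree.predict(x.reshape(-1, 1)) == y).all()

    def test_root_gini_half_for_balanced_two_classes(self):
        X = np.arange(40, dtype=float).reshape(-1, 1)
        y = np.array(["a", "b"] * 20)
        tree = cart.fit_tree(X, y, min_split=100)  # no split possible
        assert tree.nodes[0].impurity == pytest.approx(0.5)
        assert tree.n_leaves == 1

    def test_xor_layout_needs_depth_two_and_solves_it(self):
        # no single axis split separates XOR; a depth-2 tree does
        rng = np.random.default_rng(0)
        X = rng.uniform(-1, 1, size=(200, 2))
        y = np.where((X[:, 0] > 0) ^ (X[:, 1] > 0), "a", "b")
        # brute-force oracle: best single split cannot reach accuracy 1
        best_single = 0.0
        for j in (0, 1):
            for t in np.unique(X[:, j]):
                for side in (y[X[:, j] <= t], y[X[:, j] > t]):
                    pass
                pred_left = X[:, j] <= t
                for la, lb in (("a", "b"), ("b", "a")):
                    acc = ((pred_left & (y == la)) | (~pred_left & (y == lb))).mean()
                    best_single = max(best_single, acc)
        assert best_single < 1.0
        tree = cart.fit_tree(X, y, min_split=5)
        assert (tree.predict(X) == y).all()
        depths = [nd.depth for nd in tree.nodes if nd.is_leaf]
        assert max(depths) >= 2 and len(tree.nodes) >= 3

    def test_single_category_input_gives_root_only_tree(self):
        X = np.random.default_rng(1).normal(size=(50, 3))
        tree = cart.fit_tree(X, np.array(["only"] * 50))
        assert tree.n_leaves == 1

    def test_constant_predictors_give_root_only_tree(self):
        X = np.ones((60, 2))
        y = np.array(["a", "b"] * 30)
        tree = cart.fit_tree(X, y)
        assert tree.n_leaves == 1

    def test_gini_nonincreasing_along_every_root_to_leaf_path(self, default_world):
        _, _, _, _, _, cells = default_world
        X = cells[list(sw.BIOCLIM_VARIABLES)].to_numpy()
        y = cells["landcover"].to_numpy()
        tree = cart.fit_tree(X, y)

        def walk(nid, parent_weighted):
            nd = tree.nodes[nid]
            if nd.is_leaf:
                return
            left, right = tree.nodes[nd.left], tree.nodes[nd.right]
            child_weighted = (
                left.n * left.impurity + right.n * right.impurity
            ) / nd.n
            assert child_weighted <= nd.impurity + 1e-12
            walk(nd.left, left.impurity)
            walk(nd.right, right.impurity)

        walk(0, tree.nodes[0].impurity)

    def test_matches_sklearn_training_accuracy(self):
        """Independent cross-check: same greedy criterion as sklearn CART."""
        rng = np.random.default_rng(3)
        X = rng.normal(size=(300, 5))
        y = np.where(X[:, 0] + 0.5 * X[:, 2] ** 2 + rng.normal(0, 0.5, 300) > 0, "a", "b")
        ours = cart.fit_tree(X, y, min_split=20)
        ref = DecisionTreeClassifier(
            min_samples_split=20, min_samples_leaf=6, random_state=0
        ).fit(X, y)
        acc_ours = (ours.predict(X) == y).mean()
        acc_ref = ref.score(X, y)
        assert acc_ours == pytest.approx(acc_ref, abs=0.03)


class TestPruning:
    def test_noiseless_separable_data_keeps_the_full_tree(self):
        x = np.concatenate([np.linspace(0, 1, 40), np.linspace(2, 3, 40)])
        y = np.array(["a"] * 40 + ["b"] * 40)
        X = x.reshape(-1, 1)
        tree = cart.fit_tree(X, y, min_split=10)
        pruned, info = cart.prune_select_cv(tree, X, y, n_reps=20, k_folds=5, seed=0)
        assert pruned.n_leaves == tree.n_leaves == 2
        assert (pruned.predict(X) == y).all()

    def test_pure_noise_labels_prune_to_root(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(200, 4))
        y = rng.choice(["a", "b"], size=200)
        tree = cart.fit_tree(X, y, min_split=20)
        assert tree.n_leaves > 1  # the full tree overfits
        pruned, _ = cart.prune_select_cv(tree, X, y, n_reps=20, k_folds=10, seed=0)
        assert pruned.n_leaves == 1

    def test_more_label_noise_means_harder_pruning(self):
        """Rising label noise shrinks the CV-selected subtree and raises the
        CV relative-error floor."""
        rng = np.random.default_rng(5)
        n = 400
        X = rng.uniform(0, 1, size=(n, 2))
        clean = np.where((X[:, 0] > 0.5) ^ (X[:, 1] > 0.5), "a", "b")
        sizes, floors = [], []
        for noise in (0.0, 0.2, 0.45):
            y = clean.copy()
            flip = rng.random(n) < noise
            y[flip] = np.where(clean[flip] == "a", "b", "a")
            tree = cart.fit_tree(X, y, min_split=20)
            pruned, info = cart.prune_select_cv(
                tree, X, y, n_reps=10, k_folds=5, seed=1
            )
            sizes.append((tree.n_leaves, pruned.n_leaves))
            floors.append(info["cv_rel_error"].min())
        # the CV relative-error floor rises with noise ...
        assert floors[0] < floors[1] < floors[2]
        # ... and pruning always removes something once labels are noisy
        for full_size, pruned_size in sizes:
            assert pruned_size <= full_size
        assert all(p < f for f, p in sizes[1:])

    def test_pruned_tree_is_a_subtree_of_the_full_tree(self, default_world):
        _, _, _, _, _, cells = default_world
        X = cells[list(sw.BIOCLIM_VARIABLES)].to_numpy()
        y = cells["landcover"].to_numpy()
        full = cart.fit_tree(X, y)
        for alpha in cart.cost_complexity_path(full):
            pruned = cart.prune(full, alpha + 1e-9)
            assert pruned.n_leaves <= full.n_leaves

            def check(pid, fid):
                pnd, fnd = pruned.nodes[pid], full.nodes[fid]
                assert pnd.n == fnd.n
                if not pnd.is_leaf:
                    assert pnd.feature == fnd.feature
                    assert pnd.threshold == fnd.threshold
                    check(pnd.left, fnd.left)
                    check(pnd.right, fnd.right)

            check(0, 0)

    def test_invalid_rep_count_rejected(self, default_world):
        _, _, _, _, _, cells = default_world
        model = cp.fit_tree(cells, ["bio1", "bio12"])
        with pytest.raises(ValueError):
            cp.prune_by_cv(model, cells, n_reps=0)


class TestAssignLeaves:
    def test_root_only_tree_single_leaf_predicts_global_mode(self):
        y = np.array(["a"] * 20 + ["b"] * 10)
        cells = make_cells(np.ones((30, 2)), y)  # constant predictors
        model = cp.fit_tree(cells, ["bio1", "bio2"], cp.TreeControl(min_node_size=20))
        part = cp.assign_leaves(model, cells)
        assert part.leaf_ids == [1]
        assert part.leaf_category[1] == "a"
        assert part.misclassified_share["b"] == 1.0
        assert part.misclassified_share["a"] == 0.0

    def test_perfect_separation_zero_misclassified(self, small_world):
        _, _, cells = small_world
        model = cp.fit_tree(cells, list(sw.BIOCLIM_VARIABLES), cp.TreeControl())
        part = cp.assign_leaves(model, cells)
        assert part.overall_misclassified_share() == 0.0
        assert all(v == 0.0 for v in part.misclassified_share.values())

    def test_shared_envelope_minority_share_classified_differently(self):
        # two categories with the same climate: leaves predict the majority,
        # the minority is 100% "classified differently" and its share of the
        # mix equals the expected mixture weight
        rng = np.random.default_rng(7)
        X = rng.uniform(0, 1, size=(300, 2))
        y = np.where(rng.random(300) < 0.3, "minor", "major")
        cells = make_cells(X, y)
        model = cp.fit_tree(cells, ["bio1", "bio2"], cp.TreeControl(min_node_size=20))
        pruned = cp.prune_by_cv(model, cells, n_reps=10, k_folds=5, seed=0)
        part = cp.assign_leaves(pruned, cells)
        assert part.misclassified_share["minor"] == 1.0
        assert part.misclassified_share["major"] == 0.0
        assert part.overall_misclassified_share() == pytest.approx(
            (y == "minor").mean()
        )

    def test_partition_is_exhaustive_and_disjoint(self, default_partition):
        _, part = default_partition
        a = part.assignments
        assert a["cell_id"].is_unique
        assert len(a) == 1600
        assert set(a["leaf_id"]) == set(part.leaf_ids)

    def test_tree_recovers_generating_thresholds(self, default_partition):
        model, _ = default_partition
        split_thresholds = {
            model.tree.feature_names[nd.feature]: nd.threshold
            for nd in model.tree.nodes
            if not nd.is_leaf
        }
        # generating rules threshold bio1 at 22; the bio1 climate step per
        # 0.5-degree row is 0.3 degC
        assert abs(split_thresholds["bio1"] - 22.0) <= 0.3

    def test_missing_climate_rejected(self, small_world):
        _, _, cells = small_world
        broken = cells.copy()
        broken.loc[3, "bio1"] = np.nan
        model = cp.fit_tree(cells, list(sw.BIOCLIM_VARIABLES))
        with pytest.raises(ValueError, match="missing climate"):
            cp.assign_leaves(model, broken)


class TestForestCheck:
    def test_separable_data_oob_accuracy_near_one(self, small_world):
        _, _, cells = small_world
        report = cp.random_forest_check(
            cells, list(sw.BIOCLIM_VARIABLES), n_trees=100, seed=0
        )
        assert report.explained_proportion > 0.95

    def test_random_labels_oob_accuracy_near_half(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(300, 5))
        y = rng.choice(["a", "b"], size=300)
        cells = make_cells(X, y)
        report = cp.random_forest_check(
            cells, [f"bio{i + 1}" for i in range(5)], n_trees=100, seed=0
        )
        assert report.explained_proportion == pytest.approx(0.5, abs=0.1)

    def test_single_tree_forest_equals_that_trees_oob_accuracy(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(120, 3))
        y = np.where(X[:, 0] > 0, "a", "b")
        forest = cart.fit_forest(X, y, n_trees=1, seed=3)
        # independent recomputation from the single tree's OOB rows
        boot = np.random.default_rng(3).integers(0, 120, size=120)
        oob = np.setdiff1d(np.arange(120), boot)
        pred = forest.trees[0].predict(X[oob])
        assert forest.oob_accuracy() == pytest.approx((pred == y[oob]).mean())

    def test_oob_vote_counting_matches_independent_reimplementation(self):
        # with mtry = p the generator is consumed only by the bootstrap
        # draws, so the bootstrap stream can be replayed exactly and the
        # OOB vote tally recomputed from scratch
        rng = np.random.default_rng(10)
        n = 150
        X = rng.normal(size=(n, 4))
        y = np.where(X[:, 1] - X[:, 2] > 0, "a", "b")
        n_trees, seed = 25, 11
        forest = cart.fit_forest(X, y, n_trees=n_trees, mtry=4, seed=seed)
        votes = np.zeros((n, 2))
        replay = np.random.default_rng(seed)
        for tree in forest.trees:
            boot = replay.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), boot)
            pred = tree.predict(X[oob])
            for ci, c in enumerate(forest.classes_):
                votes[oob[pred == c], ci] += 1
        np.testing.assert_array_equal(votes, forest.oob_votes)
        has = votes.sum(axis=1) > 0
        manual_acc = (
            np.argmax(votes[has], axis=1) == forest.y_codes[has]
        ).mean()
        assert forest.oob_accuracy() == pytest.approx(manual_acc)

    def test_invalid_tree_count_rejected(self, small_world):
        _, _, cells = small_world
        with pytest.raises(ValueError):
            cp.random_forest_check(cells, ["bio1"], n_trees=0)


class TestAnthropogenicSensitivity:
    def test_zero_fractions_filtered_equals_all(self, small_world):
        _, _, cells = small_world
        out = cp.anthropogenic_sensitivity(
            cells, list(sw.BIOCLIM_VARIABLES), n_trees=50, seed=0, n_boot=20
        )
        assert out["n_all"] == out["n_filtered"]
        assert out["accuracy_all"] == out["accuracy_filtered"]

    def test_fraction_independent_of_correctness_slope_ci_covers_zero(self):
        rng = np.random.default_rng(12)
        n = 300
        X = rng.uniform(0, 1, size=(n, 2))
        y = np.where(X[:, 0] > 0.5, "a", "b")
        flip = rng.random(n) < 0.25  # label noise unrelated to anthro cover
        y[flip] = np.where(y[flip] == "a", "b", "a")
        cells = make_cells(X, y)
        cells["anthro_fraction"] = rng.uniform(0, 1, size=n)
        out = cp.anthropogenic_sensitivity(
            cells, ["bio1", "bio2"], n_trees=50, seed=0, n_boot=100
        )
        lo, hi = out["trend_ci"]
        assert lo <= 0.0 <= hi

    def test_flagging_exactly_the_mislabeled_cells_restores_accuracy(self):
        rng = np.random.default_rng(13)
        n = 240
        X = rng.uniform(0, 1, size=(n, 2))
        clean = np.where(X[:, 0] > 0.5, "a", "b")
        y = clean.copy()
        mislabeled = rng.random(n) < 0.2
        y[mislabeled] = np.where(clean[mislabeled] == "a", "b", "a")
        cells = make_cells(X, y)
        cells["anthro_fraction"] = np.where(mislabeled, 1.0, 0.0)
        out = cp.anthropogenic_sensitivity(
            cells, ["bio1", "bio2"], n_trees=100, seed=0, n_boot=20
        )
        assert out["accuracy_filtered"] > 0.93
        assert out["accuracy_filtered"] > out["accuracy_all"]

    def test_empty_filtered_subset_rejected(self, small_world):
        _, _, cells = small_world
        bad = cells.copy()
        bad["anthro_fraction"] = 1.0
        with pytest.raises(ValueError, match="no cells"):
            cp.anthropogenic_sensitivity(bad, ["bio1"], fraction_cutoff=0.5)
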