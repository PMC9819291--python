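"""Conditional-inference forest: trees, OOB bookkeeping, importances."""

import numpy as np
import pytest

from facit_mcid.rf_screening import (
    ConditionalForest,
    ForestSpec,
    aggregate_and_select,
    fit_conditional_tree,
    fit_forest,
    permutation_importance,
    screen_predictors,
)


def _signal_data(seed, n=144, p=20, coefs=(1.0, 0.8, 0.7, 0.6, 0.5, 0.45)):
    r = np.random.default_rng(seed)
    X = r.normal(size=(n, p))
    y = X[:, :len(coefs)] @ np.array(coefs) + r.normal(size=n)
    return X, y


class TestConditionalTree:
    def test_pure_noise_root_usually_stays_a_leaf(self):
        leaves = 0
        for s in range(40):
            r = np.random.default_rng(s)
            X = r.normal(size=(120, 8))
            y = r.normal(size=120)
            tree = fit_conditional_tree(X, y, ForestSpec(split_alpha=0.05),
                                        seed=s)
            leaves += tree.is_leaf_only
        # the Bonferroni-adjusted node test holds its level, so spurious
        # root splits occur in roughly alpha of the runs
        assert leaves >= 36

    def test_perfect_binary_separator_gives_depth_one_tree(self):
        r = np.random.default_rng(0)
        X = np.column_stack([r.normal(size=60), np.repeat([0.0, 1.0], 30)])
        y = X[:, 1] * 10.0
        tree = fit_conditional_tree(X, y, seed=1)
        assert tree.depth == 1
        assert tree.features_used == [1]
        pred = tree.predict(X)
        assert np.allclose(pred, y)

    def test_too_few_rows_make_a_single_leaf(self):
        X = np.arange(30, dtype=float).reshape(15, 2)
        y = X[:, 0]
        tree = fit_conditional_tree(X, y, ForestSpec(min_node=10), seed=0)
        assert tree.is_leaf_only
        assert np.allclose(tree.predict(X), y.mean())

    def test_constant_response_warns_and_stays_leaf(self):
        X = np.random.default_rng(0).normal(size=(50, 3))
        with pytest.warns(UserWarning, match="constant response"):
            tree = fit_conditional_tree(X, np.ones(50), seed=0)
        assert tree.is_leaf_only


class TestForest:
    def test_single_tree_forest_prediction_equals_its_tree(self):
        X, y = _signal_data(2)
        forest = fit_forest(X, y, ForestSpec(n_trees=1, seed=9))
        assert np.allclose(forest.predict(X), forest.tree(0).predict(X))

    def test_same_seed_reproduces_the_forest(self):
        X, y = _signal_data(3)
        a = fit_forest(X, y, ForestSpec(n_trees=20, seed=5))
        b = fit_forest(X, y, ForestSpec(n_trees=20, seed=5))
        assert np.array_equal(a.inbag, b.inbag)
        assert np.allclose(a.predict(X), b.predict(X))
        assert np.allclose(permutation_importance(a, X, y, seed=1),
                           permutation_importance(b, X, y, seed=1))

    def test_oob_fraction_near_bootstrap_exclusion_probability(self):
        r = np.random.default_rng(4)
        X = r.normal(size=(500, 5))
        y = r.normal(size=500)
        forest = fit_forest(X, y, ForestSpec(n_trees=60, seed=2))
        assert forest.oob_mask.mean() == pytest.approx(1 / np.e, abs=0.03)

    def test_forest_oob_loss_beats_single_tree_on_average(self):
        gaps = []
        for s in range(6):
            X, y = _signal_data(100 + s)
            forest = fit_forest(X, y, ForestSpec(n_trees=60, seed=s))
            pred = forest.oob_predict(X)
            ok = ~np.isnan(pred)
            forest_loss = np.mean((pred[ok] - y[ok]) ** 2)
            tree_losses = []
            for t in range(10):
                oob = forest.oob_mask[t]
                tp = forest.tree(t).predict(X[oob])
                tree_losses.append(np.mean((tp - y[oob]) ** 2))
            gaps.append(np.mean(tree_losses) - forest_loss)
        assert np.mean(gaps) > 0


class TestImportance:
    def test_unused_predictor_has_exactly_zero_importance(self):
        X, y = _signal_data(7, p=10, coefs=(2.0,))
        forest = fit_forest(X, y, ForestSpec(n_trees=40, seed=3))
        imp = permutation_importance(forest, X, y, seed=4)
        used = set()
        for t in range(forest.n_trees):
            used.update(forest.tree(t).features_used)
        unused = sorted(set(range(10)) - used)
        assert unused, "expected some never-used predictors"
        assert np.all(imp[unused] == 0.0)

    def test_signal_outranks_noise_in_nearly_all_runs(self):
        wins = 0
        for s in range(40):
            r = np.random.default_rng(s)
            X = r.normal(size=(150, 2))
            y = X[:, 0] + r.normal(size=150)
            forest = fit_forest(X, y, ForestSpec(n_trees=40, seed=s))
            imp = permutation_importance(forest, X, y, seed=s + 1)
            wins += imp[0] > imp[1]
        assert wins >= 38

    def test_duplicated_predictor_keeps_nonnegative_mean_importance(self):
        r = np.random.default_rng(11)
        X = r.normal(size=(200, 4))
        X[:, 3] = X[:, 0]                      # exact duplicate of the signal
        y = X[:, 0] + 0.5 * r.normal(size=200)
        imps = []
        for s in range(10):
            forest = fit_forest(X, y, ForestSpec(n_trees=50, seed=s, mtry=4))
            imps.append(permutation_importance(forest, X, y, seed=s))
        mean_imp = np.mean(imps, axis=0)
        assert mean_imp[0] >= 0 and mean_imp[3] >= 0

    def test_null_predictor_importance_centred_on_zero(self):
        # averaged over independent datasets: a fixed dataset leaves each
        # null predictor with its own spurious in-sample association, so
        # the zero-centering only holds across data draws
        rows = []
        for s in range(30):
            r = np.random.default_rng(500 + s)
            X = r.normal(size=(150, 6))
            y = X[:, 0] + r.normal(size=150)
            forest = fit_forest(X, y, ForestSpec(n_trees=40, seed=300 + s))
            rows.append(permutation_importance(forest, X, y, seed=600 + s))
        M = np.vstack(rows)
        null_mean = M[:, 1:].mean(axis=0)
        null_se = M[:, 1:].std(axis=0, ddof=1) / np.sqrt(len(M))
        assert np.all(np.abs(null_mean) <= 2.5 * np.maximum(null_se, 1e-12))


class TestAggregation:
    def test_rule_arithmetic_on_given_means(self):
        table = aggregate_and_select(np.array([[0.9, 0.5, -0.2, 0.1]]),
                                     ["a", "b", "c", "d"])
        assert table.threshold == pytest.approx(1.5 * 0.2)
        assert table.selected == ["a", "b"]
        ranks = table.frame["rank"].to_dict()
        assert ranks["a"] == 1 and ranks["c"] == 4

    def test_all_positive_with_one_near_zero_selects_the_rest(self):
        table = aggregate_and_select(np.array([[0.8, 0.4, 1e-9]]),
                                     ["a", "b", "c"])
        assert table.threshold == pytest.approx(1.5e-9)
        assert table.selected == ["a", "b"]

    def test_screen_predictors_is_deterministic(self):
        X, y = _signal_data(5, n=120, p=8, coefs=(1.0, 0.7))
        spec = ForestSpec(n_forests=5, n_trees=30, seed=42)
        a = screen_predictors(X, y, spec)
        b = screen_predictors(X, y, spec)
        assert a.frame.equals(b.frame)
        assert a.threshold == b.threshold
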