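"""Base/stacked regressors, grid search, block selection, metrics, splits."""

import numpy as np
import pandas as pd
import pytest

from pcmscreen.descriptors import FeatureMatrix
from pcmscreen.modeling import (
    TABLE1_GRIDS,
    ModelSpec,
    compute_metrics,
    grid_search,
    make_meta_features,
    split_random_holdout,
    split_target_based,
    split_temporal,
    stepwise_block_selection,
    train_base,
    train_stacked,
)


def linear_data(n=80, p=12, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    w = rng.normal(size=p)
    y = X @ w + noise * rng.normal(size=n)
    return X, y


class TestModelSpec:
    def test_invalid_algorithm(self):
        with pytest.raises(ValueError):
            ModelSpec("neural_net")

    def test_invalid_hyperparameter(self):
        with pytest.raises(ValueError):
            ModelSpec("random_forest", {"learning_rate": 0.1})

    def test_table1_grids_are_valid(self):
        for algorithm, grid in TABLE1_GRIDS.items():
            for name in grid:
                ModelSpec(algorithm, {name: grid[name][0]})


class TestTrainBase:
    def test_forest_near_interpolates_tiny_noiseless_data(self):
        # bootstrap averaging keeps some residual even with deep trees
        X, y = linear_data(n=30)
        model = train_base(ModelSpec("random_forest", {"n_estimators": 200}), X, y)
        r2, _ = compute_metrics(y, model.predict(X))
        assert r2 > 0.85

    def test_pls_exact_on_linear_data(self):
        X, y = linear_data()
        model = train_base(ModelSpec("partial_least_squares", {"n_components": 12}), X, y)
        r2, _ = compute_metrics(y, model.predict(X))
        assert r2 == pytest.approx(1.0, abs=1e-6)

    def test_seeded_determinism(self):
        X, y = linear_data(noise=0.5)
        p1 = train_base(ModelSpec("gradient_boosting"), X, y, seed=12345).predict(X)
        p2 = train_base(ModelSpec("gradient_boosting"), X, y, seed=12345).predict(X)
        assert np.array_equal(p1, p2)

    def test_pls_rank_guard(self):
        X, y = linear_data(n=20, p=5)
        with pytest.raises(ValueError, match="rank"):
            train_base(ModelSpec("partial_least_squares", {"n_components": 50}), X, y)

    def test_too_few_rows(self):
        X, y = linear_data(n=5)
        with pytest.raises(ValueError):
            train_base(ModelSpec("random_forest"), X, y)


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0])
        assert compute_metrics(y, y) == (1.0, 0.0)

    def test_mean_prediction_r2_zero(self):
        y = np.array([1.0, 2.0, 3.0, 6.0])
        r2, _ = compute_metrics(y, np.full(4, y.mean()))
        assert r2 == pytest.approx(0.0)

    def test_hand_example(self):
        # SS_tot = 2, SS_res = 2: the constant 1 is the observed mean
        r2, rmse = compute_metrics(np.array([0.0, 2.0]), np.array([1.0, 1.0]))
        assert rmse == pytest.approx(1.0)
        assert r2 == pytest.approx(0.0)
        # mirrored predictions are anticorrelated: R2 goes negative
        r2_bad, _ = compute_metrics(np.array([0.0, 2.0]), np.array([2.0, 0.0]))
        assert r2_bad == pytest.approx(-3.0)

    def test_constant_observed_flagged(self):
        with pytest.raises(ValueError, match="constant"):
            compute_metrics(np.array([2.0, 2.0]), np.array([1.0, 3.0]))


class TestGridSearch:
    def test_single_cell(self):
        X, y = linear_data(noise=0.3)
        best, table = grid_search("random_forest", {"n_estimators": [50]}, X, y, folds=3)
        assert best == {"n_estimators": 50}
        assert len(table) == 1

    def test_table_is_exhaustive(self):
        X, y = linear_data(noise=0.3)
        grid = {"n_components": [1, 2, 4, 8]}
        _, table = grid_search("partial_least_squares", grid, X, y, folds=3)
        assert len(table) == 4

    def test_pls_component_sweep_finds_near_best(self):
        X, y = linear_data(n=120, p=10, noise=0.1, seed=3)
        grid = {"n_components": [1, 2, 5, 10]}
        best, table = grid_search("partial_least_squares", grid, X, y, folds=5)
        assert table["cv_r2"].max() - table.set_index("n_components").loc[best["n_components"], "cv_r2"] <= 0.02

    def test_failing_cell_scored_minus_inf(self):
        X, y = linear_data(n=20, p=4)
        grid = {"n_components": [2, 400]}  # second cell cannot fit
        best, table = grid_search("partial_least_squares", grid, X, y, folds=3)
        assert best == {"n_components": 2}
        assert table["cv_r2"].min() == -np.inf

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            grid_search("random_forest", {}, *linear_data())


def _block_matrix(seed=0, n=100):
    """One informative block, two noise blocks, one duplicate of the noise."""
    rng = np.random.default_rng(seed)
    signal = rng.normal(size=(n, 3))
    noise_a = rng.normal(size=(n, 3))
    noise_b = rng.normal(size=(n, 3))
    y = signal @ np.array([1.5, -2.0, 0.7])
    values = np.hstack([signal, noise_a, noise_b])
    fm = FeatureMatrix(
        values=values,
        rows=[(f"c{i}", "P") for i in range(n)],
        block_index={"signal": (0, 3), "noise_a": (3, 6), "noise_b": (6, 9)},
    )
    return fm, y


class TestStepwiseSelection:
    SPEC = ModelSpec("partial_least_squares", {"n_components": 2})

    def test_informative_block_first(self):
        fm, y = _block_matrix()
        selected, trajectory = stepwise_block_selection(
            ["noise_a", "signal", "noise_b"], self.SPEC, fm, y, folds=4
        )
        assert selected[0] == "signal"
        accepted = trajectory[trajectory["accepted"]]["cv_r2"].to_numpy()
        assert np.all(np.diff(accepted) >= 0)

    def test_identical_blocks_stop_after_patience(self):
        fm, y = _block_matrix()
        fm.block_index = {"a": (0, 3), "b": (0, 3), "c": (0, 3)}
        selected, trajectory = stepwise_block_selection(
            ["a", "b", "c"], self.SPEC, fm, y, folds=4, patience=3
        )
        assert len(selected) == 1
        assert (~trajectory["accepted"]).sum() == 3

    def test_selection_never_empty(self):
        fm, y = _block_matrix()
        selected, _ = stepwise_block_selection(["noise_a"], self.SPEC, fm, y, folds=4)
        assert selected == ["noise_a"]


class TestMetaFeatures:
    def test_width_and_duplicate_bases(self):
        X, y = linear_data(n=60, noise=0.2)
        spec = ModelSpec("random_forest", {"n_estimators": 30})
        meta, banks = make_meta_features([spec, spec], X, y, k=5)
        assert meta.shape == (60, 4)
        assert np.allclose(meta[:, :2], meta[:, 2:])
        assert len(banks) == 2 and all(len(b) == 5 for b in banks)

    def test_constant_labels_give_zero_std(self):
        X, _ = linear_data(n=40)
        y = np.full(40, 5.0)
        meta, _ = make_meta_features([ModelSpec("random_forest", {"n_estimators": 10})], X, y, k=4)
        assert np.allclose(meta[:, 1], 0.0)

    def test_k_exceeding_rows_rejected(self):
        X, y = linear_data(n=8)
        with pytest.raises(ValueError):
            make_meta_features([ModelSpec("random_forest")], X, y, k=10)


class TestStacking:
    def test_deterministic_and_close_to_base(self):
        X, y = linear_data(n=150, p=10, noise=0.4, seed=11)
        train, test = np.arange(100), np.arange(100, 150)
        base = [ModelSpec("random_forest", {"n_estimators": 50})]
        meta = ModelSpec("partial_least_squares", {"n_components": 2})
        stack1 = train_stacked(base, meta, X[train], y[train], k=5, seed=12345)
        stack2 = train_stacked(base, meta, X[train], y[train], k=5, seed=12345)
        assert np.array_equal(stack1.predict(X[test]), stack2.predict(X[test]))

        base_model = train_base(base[0], X[train], y[train], seed=12345)
        _, rmse_base = compute_metrics(y[test], base_model.predict(X[test]))
        _, rmse_stack = compute_metrics(y[test], stack1.predict(X[test]))
        # a linear meta over one unbiased base cannot be much worse
        assert rmse_stack <= 1.05 * rmse_base


class TestSplits:
    def test_holdout_sizes_and_determinism(self):
        plan = split_random_holdout(10, 0.3, seed=1)
        assert len(plan.test_idx) == 3 and len(plan.train_idx) == 7
        plan2 = split_random_holdout(10, 0.3, seed=1)
        assert np.array_equal(plan.test_idx, plan2.test_idx)
        assert set(plan.train_idx) | set(plan.test_idx) == set(range(10))

    def test_holdout_validation(self):
        with pytest.raises(ValueError):
            split_random_holdout(10, 1.5)
        with pytest.raises(ValueError):
            split_random_holdout(1, 0.5)

    def test_temporal_boundary_year_goes_to_test(self):
        plan = split_temporal([2008, 2009, 2010, 2011], cut_year=2010)
        assert list(plan.train_idx) == [0, 1]
        assert list(plan.test_idx) == [2, 3]

    def test_temporal_missing_year_goes_to_train(self):
        plan = split_temporal([None, 2012])
        assert list(plan.train_idx) == [0]

    def test_temporal_one_sided_warns(self):
        with pytest.warns(UserWarning):
            split_temporal([2000, 2001], cut_year=2010)

    def test_temporal_fixture_counts(self, rng):
        years = [2005] * 70 + [2012] * 30
        plan = split_temporal(years, cut_year=2010)
        assert len(plan.train_idx) == 70 and len(plan.test_idx) == 30

    def test_target_based_two_proteins(self):
        desc = {"A": np.array([0.0, 0.0]), "B": np.array([5.0, 5.0])}
        plan = split_target_based(["A"] * 7 + ["B"] * 3, desc, 0.7, seed=1)
        targets = np.array(["A"] * 7 + ["B"] * 3)
        assert set(targets[plan.train_idx]) & set(targets[plan.test_idx]) == set()
        assert len(set(targets[plan.train_idx])) == 1

    def test_target_based_share_near_requested(self, rng):
        proteins = [f"P{i}" for i in range(20)]
        desc = {p: rng.normal(size=6) for p in proteins}
        target_ids = [p for p in proteins for _ in range(int(rng.integers(10, 30)))]
        plan = split_target_based(target_ids, desc, 0.7, seed=12345)
        share = len(plan.train_idx) / len(target_ids)
        assert abs(share - 0.7) <= 0.10
        t = np.array(target_ids)
        assert set(t[plan.train_idx]) & set(t[plan.test_idx]) == set()

    def test_target_based_determinism_and_single_protein(self):
        desc = {"A": np.zeros(3), "B": np.ones(3), "C": np.full(3, 2.0)}
        ids = ["A", "B", "C"] * 5
        p1 = split_target_based(ids, desc, 0.7, seed=7)
        p2 = split_target_based(ids, desc, 0.7, seed=7)
        assert np.array_equal(p1.train_idx, p2.train_idx)
        with pytest.raises(ValueError):
            split_target_based(["A"] * 5, desc, 0.7)
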