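import numpy as np
import pandas as pd
import pytest

from traitrank.models import (
    RangeScaler,
    fit_mlp,
    fit_rbf,
    fit_stepwise,
    fit_tree_ensembles,
    kfold_indices,
    normalize_inputs,
    r_squared,
    split_train_validation,
)
from traitrank.models import RBFNetwork


class TestSplits:
    @pytest.mark.parametrize("n,frac,expected", [(500, 0.8, 400), (500, 0.5, 250), (10, 0.8, 8)])
    def test_split_sizes(self, n, frac, expected):
        tr, va = split_train_validation(n, frac, seed=0)
        assert len(tr) == expected and len(va) == n - expected
        assert not set(tr) & set(va)
        assert sorted(set(tr) | set(va)) == list(range(n))

    def test_split_deterministic(self):
        assert np.array_equal(
            split_train_validation(10, 0.8, seed=1)[0],
            split_train_validation(10, 0.8, seed=1)[0],
        )

    def test_split_fraction_bounds(self):
        for frac in (0, 1, 1.5):
            with pytest.raises(ValueError):
                split_train_validation(10, frac)

    @pytest.mark.parametrize("n,k,sizes", [(500, 10, {50}), (10, 10, {1}), (7, 3, {3, 2})])
    def test_kfold_partition(self, n, k, sizes):
        folds = kfold_indices(n, k, seed=0)
        assert len(folds) == k
        assert {len(f) for f in folds} == sizes
        assert sorted(np.concatenate(folds).tolist()) == list(range(n))

    def test_kfold_bounds(self):
        with pytest.raises(ValueError):
            kfold_indices(5, 6)
        with pytest.raises(ValueError):
            kfold_indices(5, 1)


class TestRSquared:
    def test_hand_values(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r_squared(y, y) == 1.0
        assert r_squared(y, np.full(3, y.mean())) == 0.0
        assert r_squared(y, np.array([1.0, 2.0, 4.0])) == pytest.approx(0.5)

    def test_constant_observed_rejected(self):
        with pytest.raises(ValueError):
            r_squared([1, 1, 1], [1, 2, 3])

    def test_agrees_with_mse_over_variance(self):
        rng = np.random.default_rng(0)
        y, yhat = rng.normal(size=50), rng.normal(size=50)
        alt = 1.0 - np.mean((y - yhat) ** 2) / np.var(y)
        assert r_squared(y, yhat) == pytest.approx(alt, abs=1e-12)


class TestRangeScaler:
    def test_maps_training_range_to_unit_interval(self):
        df = pd.DataFrame({"x": [0.0, 5.0, 10.0]})
        scaler, Z = normalize_inputs(df)
        assert Z.ravel().tolist() == [-1.0, 0.0, 1.0]

    def test_out_of_range_values_allowed(self):
        scaler = RangeScaler().fit(pd.DataFrame({"x": [0.0, 10.0]}))
        assert scaler.transform(pd.DataFrame({"x": [20.0]}))[0, 0] == pytest.approx(3.0)

    def test_round_trip(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("abcd"))
        scaler, Z = normalize_inputs(df)
        assert np.allclose(scaler.inverse_transform(Z), df.to_numpy(), atol=1e-12)

    def test_constant_column_named_in_error(self):
        df = pd.DataFrame({"good": [1.0, 2.0], "flat": [3.0, 3.0]})
        with pytest.raises(ValueError, match="flat"):
            RangeScaler().fit(df)


class TestStepwise:
    def test_perfect_predictor_selected(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(100, 3)), columns=["a", "b", "y_copy"])
        y = X["y_copy"].to_numpy()
        fit = fit_stepwise(X.iloc[:80], y[:80], X.iloc[80:], y[80:])
        assert "y_copy" in fit.predictors
        assert fit.r2_train == pytest.approx(1.0)
        assert fit.importance["y_copy"] > 0

    def test_null_selection_rate_matches_family_wise_bound(self):
        # min-p forward entry at 0.05 over 10 null predictors selects >= 1
        # predictor with probability ~ 1 - 0.95^10 = 0.401
        hits = 0
        n_seeds = 120
        for s in range(n_seeds):
            rng = np.random.default_rng(s)
            X = pd.DataFrame(rng.normal(size=(500, 10)),
                             columns=[f"x{i}" for i in range(10)])
            y = rng.normal(size=500)
            fit = fit_stepwise(X.iloc[:400], y[:400], X.iloc[400:], y[400:])
            hits += bool(fit.predictors)
        rate = hits / n_seeds
        assert rate == pytest.approx(1 - 0.95**10, abs=0.12)

    def test_preconditions(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            fit_stepwise(X, [1, 2, 3], X, [1, 2, 3])


class TestMLP:
    def test_learns_linear_target(self, linear_xy):
        X, y = linear_xy
        fit = fit_mlp(X.iloc[:240], y[:240], X.iloc[240:], y[240:], seed=0, alpha=1e-4)
        assert fit.r2_validation > 0.99

    def test_seed_determinism(self, linear_xy):
        X, y = linear_xy
        a = fit_mlp(X.iloc[:240], y[:240], X.iloc[240:], y[240:], seed=5)
        b = fit_mlp(X.iloc[:240], y[:240], X.iloc[240:], y[240:], seed=5)
        assert np.array_equal(
            a.details["weights_input_hidden"], b.details["weights_input_hidden"]
        )
        assert a.r2_validation == b.r2_validation

    def test_exposes_single_hidden_layer_weights(self, linear_xy):
        X, y = linear_xy
        fit = fit_mlp(X.iloc[:240], y[:240], X.iloc[240:], y[240:], hidden_neurons=7, seed=0)
        assert fit.details["weights_input_hidden"].shape == (3, 7)
        assert fit.details["weights_hidden_output"].shape == (7, 1)


class TestRBF:
    def test_default_grid_has_231_cells(self):
        from traitrank.study import StudyConfig

        cfg = StudyConfig()
        assert len(cfg.rbf_neurons) * len(cfg.rbf_radii) == 11 * 21 == 231

    def test_single_wide_center_is_nearly_constant(self):
        rng = np.random.default_rng(2)
        Z = rng.uniform(-1, 1, size=(100, 2))
        y = rng.normal(size=100)
        net = RBFNetwork.fit(Z, y, centers=np.zeros((1, 2)), radius=1e3)
        preds = net.predict(Z)
        assert np.std(preds) < 0.05 * np.std(y)

    def test_fits_smooth_nonlinear_function(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame({"x": rng.uniform(-3, 3, 400), "z": rng.normal(size=400)})
        y = np.sin(X["x"].to_numpy())
        fit = fit_rbf(X.iloc[:300], y[:300], X.iloc[300:], y[300:],
                      neurons=(6, 10), radii=(0.1, 0.3, 1.0), seed=0)
        assert fit.r2_validation > 0.9

    def test_grid_choice_deterministic(self, linear_xy):
        X, y = linear_xy
        kwargs = dict(neurons=(4, 8), radii=(0.5, 1.0), seed=9)
        a = fit_rbf(X.iloc[:240], y[:240], X.iloc[240:], y[240:], **kwargs)
        b = fit_rbf(X.iloc[:240], y[:240], X.iloc[240:], y[240:], **kwargs)
        assert a.details == b.details
        assert a.r2_validation == b.r2_validation

    def test_too_many_centers_rejected(self, linear_xy):
        X, y = linear_xy
        with pytest.raises(ValueError):
            fit_rbf(X.iloc[:20], y[:20], X.iloc[20:], y[20:], neurons=(50,), radii=(1.0,))


class TestTreeEnsembles:
    def test_noiseless_signal_recovered_by_all_methods(self):
        rng = np.random.default_rng(0)
        # random forest sees only 1 of 4 predictors per split, so it needs
        # more data than the others to pin the signal down
        X = pd.DataFrame(rng.normal(size=(2000, 4)), columns=list("abcd"))
        y = X["a"].to_numpy()
        for method in ("tree", "bagging", "random_forest", "boosting"):
            fit = fit_tree_ensembles(
                X.iloc[:1600], y[:1600], X.iloc[1600:], y[1600:], method, n_trees=100, seed=0
            )
            assert fit.r2_validation > 0.95, method

    def test_pure_noise_target_near_zero_validation_r2(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(500, 10)), columns=[f"x{i}" for i in range(10)])
        y = rng.normal(size=500)
        for method, lo in (("bagging", -0.15), ("random_forest", -0.15), ("boosting", -0.5)):
            fit = fit_tree_ensembles(
                X.iloc[:400], y[:400], X.iloc[400:], y[400:], method, n_trees=200, seed=0
            )
            # boosting keeps fitting noise, so its band is wider
            assert lo < fit.r2_validation < 0.15, method

    def test_forest_beats_single_tree_in_majority(self):
        wins = 0
        n_rep = 9
        for s in range(n_rep):
            rng = np.random.default_rng([7, s])
            X = pd.DataFrame(rng.normal(size=(300, 5)), columns=list("abcde"))
            y = X["a"].to_numpy() + 0.5 * X["b"].to_numpy() ** 2 + rng.normal(size=300)
            tree = fit_tree_ensembles(X.iloc[:240], y[:240], X.iloc[240:], y[240:],
                                      "tree", seed=0)
            rf = fit_tree_ensembles(X.iloc[:240], y[:240], X.iloc[240:], y[240:],
                                    "random_forest", n_trees=200, seed=0)
            wins += rf.r2_validation > tree.r2_validation
        assert wins > n_rep / 2

    def test_unknown_method_rejected(self, linear_xy):
        X, y = linear_xy
        with pytest.raises(ValueError):
            fit_tree_ensembles(X, y, X, y, method="extra_trees")

    def test_cross_validation_r2_reported(self, linear_xy):
        X, y = linear_xy
        fit = fit_tree_ensembles(X.iloc[:240], y[:240], X.iloc[240:], y[240:],
                                 "tree", seed=0, cv_folds=5)
        assert np.isfinite(fit.r2_cv)
        assert fit.r2_cv > 0.9
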