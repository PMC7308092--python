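"""Two-layer stacking: ridge/GCV, shared CV scheme, double-coding,
forest combiner, opportunistic prediction."""

import numpy as np
import pytest

import oppstack as op
from oppstack.stacking import RidgeGCV, _tune_forest


class TestRidgeGCV:
    def test_small_lambda_approaches_ols(self, rng):
        X = rng.standard_normal((200, 5))
        y = X @ rng.standard_normal(5) + 0.1 * rng.standard_normal(200)
        model = RidgeGCV(lam=1e-8).fit(X, y)
        ols = np.linalg.lstsq(np.column_stack([np.ones(200), X]), y, rcond=None)[0]
        np.testing.assert_allclose(model.coef_, ols[1:], atol=1e-6)

    def test_huge_lambda_shrinks_to_near_zero(self, rng):
        X = rng.standard_normal((100, 5))
        y = X @ np.ones(5) + rng.standard_normal(100)
        ols_norm = np.linalg.norm(np.linalg.lstsq(X - X.mean(0), y - y.mean(),
                                                  rcond=None)[0])
        model = RidgeGCV(lam=1e5).fit(X, y)
        assert np.linalg.norm(model.coef_ * model.scaler_.scale_) < 0.01 * ols_norm

    def test_gcv_path_matches_hat_matrix_oracle(self, rng):
        """SVD-based GCV equals a direct fit/hat-trace/residual evaluation."""
        X = rng.standard_normal((30, 5))
        y = rng.standard_normal(30)
        spec = op.RidgeSpec(np.logspace(-2, 3, 25))
        model = RidgeGCV(spec).fit(X, y)
        Xs = (X - X.mean(0)) / X.std(0)
        yc = y - y.mean()
        n = 30
        oracle = []
        for lam in spec.lambda_grid:
            H = Xs @ np.linalg.solve(Xs.T @ Xs + lam * np.eye(5), Xs.T)
            resid = yc - H @ yc
            df = 1.0 + np.trace(H)
            oracle.append((resid @ resid / n) / (1 - df / n) ** 2)
        oracle = np.array(oracle)
        np.testing.assert_allclose(model.gcv_path_, oracle, atol=1e-8)
        assert model.lambda_ == spec.lambda_grid[np.argmin(oracle)]

    def test_degenerate_inputs_rejected(self, rng):
        X = rng.standard_normal((10, 3))
        with pytest.raises(ValueError):
            RidgeGCV().fit(X, np.ones(10))  # constant target
        Xnan = X.copy()
        Xnan[0, 0] = np.nan
        with pytest.raises(ValueError):
            RidgeGCV().fit(Xnan, rng.standard_normal(10))


class TestCVScheme:
    def test_folds_partition_subjects_each_repeat(self):
        cv = op.CVScheme(53, n_folds=7, n_repeats=3, seed=2)
        for rep in range(3):
            seen = np.concatenate([cv.test_indices(rep, f) for f in range(7)])
            np.testing.assert_array_equal(np.sort(seen), np.arange(53))
            for f in range(7):
                tr = set(cv.train_indices(rep, f))
                te = set(cv.test_indices(rep, f))
                assert not tr & te and len(tr | te) == 53

    def test_deterministic_given_seed(self):
        a = op.CVScheme(40, 5, 2, seed=9)
        b = op.CVScheme(40, 5, 2, seed=9)
        np.testing.assert_array_equal(a.fold_of, b.fold_of)


class TestGenerateOOF:
    def test_noiseless_linear_block_near_perfect(self):
        cfg = op.SimulationConfig(
            n_subjects=150,
            block_specs=[op.BlockSpec("lin", 5, shared_signal_weight=1.0,
                                      noise_sd=1e-8)],
            seed=1)
        ds = op.generate_multimodal(cfg)
        cv = op.CVScheme(150, 5, 1, seed=0)
        sp = op.generate_oof(ds, cv)
        assert np.mean(np.abs(sp.values[0, :, 0] - ds.age)) < 0.1

    def test_pure_noise_block_at_chance(self):
        ratios = []
        for seed in range(5):
            cfg = op.SimulationConfig(
                n_subjects=200,
                block_specs=[op.BlockSpec("noise", 10, shared_signal_weight=0.0,
                                          private_signal_weight=0.0,
                                          noise_sd=1.0)],
                seed=seed)
            ds = op.generate_multimodal(cfg)
            cv = op.CVScheme(200, 5, 1, seed=seed)
            sp = op.generate_oof(ds, cv)
            mae_block = np.mean(np.abs(sp.values[0, :, 0] - ds.age))
            dummy = np.mean([
                np.mean(np.abs(ds.age[cv.train_indices(0, f)].mean()
                               - ds.age[cv.test_indices(0, f)]))
                for f in range(5)])
            ratios.append(mae_block / dummy)
        assert abs(np.mean(ratios) - 1.0) < 0.1

    def test_missing_cells_flagged_every_repeat(self, small_dataset, small_cv):
        sp = op.generate_oof(small_dataset, small_cv)
        j = small_dataset.block_names.index("mri")
        unobs = ~small_dataset.blocks["mri"].mask
        assert unobs.any()
        assert np.isnan(sp.values[:, unobs, j]).all()
        obs = small_dataset.blocks["mri"].mask
        assert not np.isnan(sp.values[:, obs, j]).any()


class TestDoubleCode:
    def test_worked_example(self):
        values = np.array([[23.5], [np.nan], [60.1]])
        coded = op.double_code(values)
        np.testing.assert_array_equal(coded[:, 0], [23.5, -1000.0, 60.1])
        np.testing.assert_array_equal(coded[:, 1], [23.5, 1000.0, 60.1])

    def test_no_missing_copies_identical(self, rng):
        values = rng.uniform(18, 88, size=(10, 3))
        coded = op.double_code(values)
        np.testing.assert_array_equal(coded[:, 0::2], coded[:, 1::2])

    def test_all_missing_block_constant_sentinels(self):
        values = np.column_stack([np.full(5, 30.0), np.full(5, np.nan)])
        coded = op.double_code(values)
        assert np.all(coded[:, 2] == -1000.0) and np.all(coded[:, 3] == 1000.0)

    def test_sentinel_collision_rejected(self):
        with pytest.raises(ValueError, match="sentinel"):
            op.double_code(np.array([[1000.0]]))


class TestStacker:
    def test_constant_target_predicted_exactly(self, small_dataset, small_cv,
                                               tiny_forest_spec):
        sp = op.generate_oof(small_dataset, small_cv)
        y = np.full(small_dataset.n_subjects, 50.0)
        sm = op.fit_stacker(sp, y, small_cv, tiny_forest_spec, tune=False)
        np.testing.assert_allclose(sm.oof_values, 50.0)

    def test_layer2_splits_match_layer1(self, small_dataset, small_cv,
                                        tiny_forest_spec):
        # split consistency is structural: both layers consume the same
        # CVScheme object, and a mismatched scheme is rejected
        sp = op.generate_oof(small_dataset, small_cv)
        other = op.CVScheme(small_dataset.n_subjects, 5, 2, seed=99)
        with pytest.raises(ValueError, match="different CV scheme"):
            op.fit_stacker(sp, small_dataset.age, other, tiny_forest_spec)

    def test_sentinel_invariance(self, small_dataset, small_cv):
        """Forest predictions only need sentinel separability, not scale."""
        spec = op.ForestSpec(n_trees=30, depth_grid=(4,),
                             max_features_grid=(1.0,), seed=3)
        sp = op.generate_oof(small_dataset, small_cv)
        sm1 = op.fit_stacker(sp, small_dataset.age, small_cv, spec,
                             sentinels=(-1000.0, 1000.0), tune=False)
        sm2 = op.fit_stacker(sp, small_dataset.age, small_cv, spec,
                             sentinels=(-1e6, 1e6), tune=False)
        np.testing.assert_allclose(sm1.oof_values, sm2.oof_values)

    def test_tune_prefers_simpler_on_ties(self, rng):
        # constant features: every grid cell scores identically
        X = np.ones((40, 3))
        y = rng.uniform(0, 1, 40)
        spec = op.ForestSpec(n_trees=5, depth_grid=(4, 6, None),
                             max_features_grid=("sqrt", 1.0), seed=0)
        depth, mf = _tune_forest(X, y, spec, seed=0)
        assert depth == 4 and mf == "sqrt"


class TestOpportunisticPredict:
    def test_complete_subject_identical_to_training_path(self, small_dataset,
                                                         small_cv):
        spec = op.ForestSpec(n_trees=30, depth_grid=(None,),
                             max_features_grid=(1.0,), seed=1)
        model = op.StackedAgeModel(small_dataset, forest_spec=spec)
        res = model.fit(small_cv, tune=False)
        blocks = {name: (blk.X, blk.mask)
                  for name, blk in small_dataset.blocks.items()}
        preds = res.predict(blocks)
        # manual path: layer-1 full-data models -> double-code -> forests
        values = np.full((small_dataset.n_subjects, 2), np.nan)
        for j, name in enumerate(small_dataset.block_names):
            blk = small_dataset.blocks[name]
            values[blk.mask, j] = res.stacked_model.layer1_models[name].predict(
                blk.X[blk.mask])
        coded = op.double_code(values, None, (-1000.0, 1000.0))
        expected = np.mean([f.predict(coded)
                            for f in res.stacked_model.forests], axis=0)
        np.testing.assert_array_equal(preds, expected)

    def test_all_missing_subject_rejected(self, small_dataset, small_cv,
                                          tiny_forest_spec):
        model = op.StackedAgeModel(small_dataset, forest_spec=tiny_forest_spec)
        res = model.fit(small_cv, tune=False)
        blocks = {"meg": (small_dataset.blocks["meg"].X[:3],
                          np.zeros(3, dtype=bool))}
        with pytest.raises(ValueError, match="zero observed"):
            res.predict(blocks)

    def test_unknown_block_rejected(self, small_dataset, small_cv,
                                    tiny_forest_spec):
        model = op.StackedAgeModel(small_dataset, forest_spec=tiny_forest_spec)
        res = model.fit(small_cv, tune=False)
        with pytest.raises(ValueError, match="unknown block"):
            res.predict({"pet": (np.zeros((2, 3)), np.ones(2, dtype=bool))})


class TestMissingnessDiagnostic:
    def test_no_missingness_is_an_error(self, small_cv):
        cfg = op.SimulationConfig(
            n_subjects=120,
            block_specs=[op.BlockSpec("a", 5)], seed=0)
        ds = op.generate_multimodal(cfg)
        sp = op.generate_oof(ds, small_cv)
        with pytest.raises(ValueError, match="no missingness"):
            op.missingness_diagnostic(sp, ds.age, small_cv)

    def test_returns_paired_fold_table(self, small_dataset, small_cv,
                                       tiny_forest_spec):
        sp = op.generate_oof(small_dataset, small_cv)
        out = op.missingness_diagnostic(sp, small_dataset.age, small_cv,
                                        tiny_forest_spec)
        assert len(out) == small_cv.n_splits
        assert {"mae_diagnostic", "mae_dummy"} <= set(out.columns)


def test_summary_reports_all_models(small_dataset, small_cv, tiny_forest_spec):
    model = op.StackedAgeModel(small_dataset, forest_spec=tiny_forest_spec)
    res = model.fit(small_cv, tune=False)
    text = res.summary()
    for token in ("stacked", "solo_meg", "solo_mri", "dummy"):
        assert token in text
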