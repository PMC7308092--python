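"""Scoring, paired comparisons, rank statistics and variable importance."""

import numpy as np
import pytest
from sklearn.ensemble import RandomForestRegressor
from sklearn.tree import DecisionTreeRegressor

import oppstack as op
from oppstack.evaluation import _perm_rng


KEY = (0, 10, 10, 0)  # n_subjects placeholder, 10 folds x 10 repeats


def _scores(name, values):
    return op.FoldScores(name, values, KEY)


class TestMae:
    def test_hand_arithmetic(self):
        assert op.mae([25, 35], [20, 40]) == 5.0
        assert op.mae([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_matches_loop_oracle(self, rng):
        pred = rng.standard_normal(100)
        truth = rng.standard_normal(100)
        acc = 0.0
        for p, t in zip(pred, truth):
            acc += abs(p - t)
        assert op.mae(pred, truth) == pytest.approx(acc / 100, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            op.mae([], [])


class TestDummy:
    def test_hand_arithmetic(self):
        preds = op.dummy_baseline([20, 40, 60], [40, 60])
        np.testing.assert_array_equal(preds, [40.0, 40.0])
        assert op.mae(preds, [40, 60]) == 10.0

    def test_uniform_age_mad(self, rng):
        # mean absolute deviation of U(18, 88) about its mean is range/4
        y = rng.uniform(18, 88, 200000)
        preds = op.dummy_baseline(y, y)
        assert abs(op.mae(preds, y) - 17.5) < 0.5


class TestPairedCompare:
    def test_self_comparison_is_zero(self, rng):
        a = _scores("a", rng.uniform(5, 10, 100))
        cmp_ = op.paired_compare(a, a)
        assert (cmp_.mean, cmp_.sd, cmp_.p2_5, cmp_.p97_5) == (0, 0, 0, 0)
        assert cmp_.pr_better == 0.0  # strict inequality: ties are not wins

    def test_uniform_improvement(self, rng):
        ref = _scores("ref", rng.uniform(5, 10, 100))
        a = _scores("a", ref.values - 1.0)
        cmp_ = op.paired_compare(a, ref)
        assert cmp_.mean == pytest.approx(-1.0) and cmp_.pr_better == 1.0

    def test_antisymmetry_and_percentile_oracle(self, rng):
        a = _scores("a", rng.standard_normal(100) + 7)
        b = _scores("b", rng.standard_normal(100) + 7)
        ab = op.paired_compare(a, b)
        ba = op.paired_compare(b, a)
        assert ab.mean == pytest.approx(-ba.mean)
        # manual sorted-array percentile with linear interpolation
        diff = np.sort(a.values - b.values)
        for q, got in ((2.5, ab.p2_5), (97.5, ab.p97_5)):
            pos = q / 100 * (len(diff) - 1)
            lo, hi = int(np.floor(pos)), int(np.ceil(pos))
            expect = diff[lo] + (pos - lo) * (diff[hi] - diff[lo])
            assert got == pytest.approx(expect, abs=1e-12)

    def test_misaligned_schemes_rejected(self, rng):
        a = _scores("a", rng.uniform(5, 10, 100))
        b = op.FoldScores("b", rng.uniform(5, 10, 25), (0, 5, 5, 0))
        with pytest.raises(ValueError):
            op.paired_compare(a, b)


class TestRankModels:
    def test_strictly_better_model_always_rank_one(self, rng):
        base = rng.uniform(5, 10, 100)
        best = _scores("best", base - 2)
        other = _scores("other", base)
        table = op.rank_models([best, other])
        row = table[(table.model == "best") & (table["rank"] == 1.0)]
        assert row.n_splits.item() == 100
        assert table.attrs["pairwise_wins"][("best", "other")] == 1.0

    def test_identical_models_tied_at_average_rank(self, rng):
        vals = rng.uniform(5, 10, 100)
        table = op.rank_models([_scores("a", vals), _scores("b", vals.copy())])
        assert set(table["rank"]) == {1.5}

    def test_three_models_match_brute_force(self, rng):
        mats = {n: rng.uniform(5, 10, 100) for n in "abc"}
        table = op.rank_models([_scores(n, v) for n, v in mats.items()])
        wins = table.attrs["pairwise_wins"]
        for i in "abc":
            for j in "abc":
                if i != j:
                    brute = np.mean([x < y for x, y in zip(mats[i], mats[j])])
                    assert wins[(i, j)] == pytest.approx(brute)


class TestPermutationImportance:
    def test_constant_feature_zero_importance(self, rng):
        X = np.column_stack([rng.standard_normal(200), np.ones(200)])
        y = X[:, 0]
        forest = RandomForestRegressor(n_estimators=20, random_state=0).fit(X, y)
        imp = op.permutation_importance(forest, X, y, k=10, seed=0)
        assert imp[1] == 0.0

    def test_matches_fixed_permutation_oracle(self, rng):
        """Same permutation stream, independent recomputation, 1e-12."""
        X = rng.standard_normal((100, 1))
        y = X[:, 0] + 0.1 * rng.standard_normal(100)
        forest = RandomForestRegressor(n_estimators=10, random_state=0).fit(X, y)
        k, seed = 5, 42
        imp = op.permutation_importance(forest, X, y, k=k, seed=seed)
        baseline = np.mean(np.abs(forest.predict(X) - y))
        drops = []
        for rep in range(k):
            Xp = X.copy()
            Xp[:, 0] = _perm_rng(seed, 0, rep).permutation(Xp[:, 0])
            drops.append(np.mean(np.abs(forest.predict(Xp) - y)) - baseline)
        assert abs(imp[0] - np.mean(drops)) < 1e-12

    def test_informative_beats_noise_feature(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((150, 2))
            y = 2 * X[:, 0] + 0.3 * rng.standard_normal(150)
            forest = RandomForestRegressor(n_estimators=30,
                                           random_state=seed).fit(X, y)
            imp = op.permutation_importance(forest, X, y, k=20, seed=seed)
            hits += imp[0] > imp[1]
        assert hits >= 19  # >= 95% of 20 seeds

    def test_k_validated(self, rng):
        with pytest.raises(ValueError):
            op.permutation_importance(None, np.zeros((2, 1)), np.zeros(2), k=0)


class TestMDI:
    def test_single_feature_gets_full_share(self, rng):
        X = rng.standard_normal((100, 1))
        y = X[:, 0]
        forest = RandomForestRegressor(n_estimators=10, random_state=0).fit(X, y)
        np.testing.assert_allclose(op.mdi_importance(forest), [1.0])

    def test_constant_feature_zero_share_and_normalization(self, rng):
        X = np.column_stack([rng.standard_normal(200), np.ones(200)])
        y = X[:, 0]
        forest = RandomForestRegressor(n_estimators=20, random_state=0).fit(X, y)
        mdi = op.mdi_importance(forest)
        assert mdi[1] == 0.0 and mdi.sum() == pytest.approx(1.0)

    def test_stump_matches_enumerated_best_split(self):
        # 1-D step data: enumerate all candidate thresholds by hand
        X = np.arange(10, dtype=float)[:, None]
        y = np.array([0.0] * 5 + [1.0] * 5)
        tree = DecisionTreeRegressor(max_depth=1, random_state=0).fit(X, y)
        n = len(y)
        best_gain = 0.0
        for cut in range(1, n):
            left, right = y[:cut], y[cut:]
            gain = y.var() - (len(left) * left.var() + len(right) * right.var()) / n
            best_gain = max(best_gain, gain)
        got_gain = (tree.tree_.impurity[0]
                    - (tree.tree_.n_node_samples[1] * tree.tree_.impurity[1]
                       + tree.tree_.n_node_samples[2] * tree.tree_.impurity[2]) / n)
        assert got_gain == pytest.approx(best_gain, abs=1e-12)
        np.testing.assert_allclose(op.mdi_importance(tree), [1.0])

    def test_unfitted_rejected(self):
        with pytest.raises(ValueError):
            op.mdi_importance(object())


class TestPartialDependence:
    def test_ignored_feature_flat(self, rng):
        X = np.column_stack([rng.standard_normal(100), np.zeros(100)])
        y = X[:, 0]
        forest = RandomForestRegressor(n_estimators=20, random_state=0).fit(X, y)
        curve = op.partial_dependence(forest, X, 1, np.linspace(-2, 2, 7))
        assert np.ptp(curve) < 1e-12

    def test_clamp_single_row_equals_prediction(self, rng):
        X = rng.standard_normal((1, 2))
        forest = RandomForestRegressor(n_estimators=5, random_state=0).fit(
            np.vstack([X, X + 1]), [0.0, 1.0])
        val = op.partial_dependence(forest, X, 0, [X[0, 0]])
        assert val[0] == forest.predict(X)[0]

    def test_additive_truth_gives_additive_surface(self, rng):
        X = rng.uniform(-1, 1, (400, 2))
        y = np.sin(2 * X[:, 0]) + X[:, 1] ** 2
        forest = RandomForestRegressor(n_estimators=50, random_state=0).fit(X, y)
        g0 = np.linspace(-0.8, 0.8, 6)
        g1 = np.linspace(-0.8, 0.8, 6)
        surf = op.partial_dependence(forest, X, (0, 1), (g0, g1))
        c0 = op.partial_dependence(forest, X, 0, g0)
        c1 = op.partial_dependence(forest, X, 1, g1)
        recon = c0[:, None] + c1[None, :] - surf.mean()
        dev = np.max(np.abs(surf - recon))
        assert dev < 0.1 * np.ptp(surf)

    def test_unknown_feature_rejected(self, rng):
        with pytest.raises(ValueError):
            op.partial_dependence(None, np.zeros((3, 2)), 5, [0.0])


def test_out_of_sample_importance_ranks_informative_first(rng):
    X = rng.standard_normal((150, 2))
    y = 2 * X[:, 0] + 0.3 * rng.standard_normal(150)
    cv = op.CVScheme(150, n_folds=5, n_repeats=1, seed=0)

    def fit(Xtr, ytr):
        return RandomForestRegressor(n_estimators=20, random_state=0).fit(Xtr, ytr)

    table = op.permutation_importance_oos(fit, X, y, cv, k=10, seed=0)
    assert table.importance_mean[0] > table.importance_mean[1]
    assert len(table) == 2 and "importance_sd" in table
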