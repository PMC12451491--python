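"""Suitability-model engine: fitting, evaluation, thresholding.

The AUC and threshold routines are checked against brute-force oracles;
the fit against sign, ridge-limit and rescaling invariances; and the
whole engine against virtual species with known niches.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from montrange import sdm
from montrange.grid import build_grid
from montrange.world import EnvStack, gaussian_suitability, simulate_species


def brute_force_auc(pos, neg):
    pos = np.asarray(pos)[:, None]
    neg = np.asarray(neg)[None, :]
    return ((pos > neg) + 0.5 * (pos == neg)).mean()


def brute_force_threshold(pos, neg):
    pos = np.asarray(pos, float)
    neg = np.asarray(neg, float)
    best_t, best_v = None, -np.inf
    for t in np.sort(np.unique(np.concatenate([pos, neg]))):
        # integer objective (scaled by the two set sizes) keeps the
        # comparison exact under ties
        v = (pos >= t).sum() * len(neg) + (neg < t).sum() * len(pos)
        if v > best_v:
            best_t, best_v = t, v
    return best_t


class TestAuc:
    def test_perfect_separation(self):
        assert sdm.auc([0.9, 0.8], [0.2, 0.1]) == 1.0

    def test_identical_sets(self):
        assert sdm.auc([0.5, 0.2], [0.5, 0.2]) == 0.5

    def test_hand_example(self):
        assert sdm.auc([0.9, 0.4], [0.5, 0.1]) == pytest.approx(0.75)

    @given(
        st.lists(st.integers(0, 20), min_size=1, max_size=50),
        st.lists(st.integers(0, 20), min_size=1, max_size=50),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_pairwise_oracle(self, pos, neg):
        # integer scores force many ties, stressing the midrank path
        pos = np.asarray(pos) / 20.0
        neg = np.asarray(neg) / 20.0
        assert sdm.auc(pos, neg) == pytest.approx(brute_force_auc(pos, neg))


class TestThreshold:
    def test_hand_example(self):
        assert sdm.select_threshold([0.8, 0.7], [0.3, 0.2]) == pytest.approx(0.7)

    def test_perfect_separation_gives_smallest_presence_score(self):
        assert sdm.select_threshold([0.6, 0.9], [0.1, 0.2]) == pytest.approx(0.6)

    def test_identical_sets_give_smallest_candidate(self):
        assert sdm.select_threshold([0.4, 0.7], [0.4, 0.7]) == pytest.approx(0.4)

    @given(
        st.lists(st.integers(0, 15), min_size=1, max_size=40),
        st.lists(st.integers(0, 15), min_size=1, max_size=40),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_exhaustive_scan(self, pos, neg):
        pos = np.asarray(pos) / 15.0
        neg = np.asarray(neg) / 15.0
        assert sdm.select_threshold(pos, neg) == pytest.approx(brute_force_threshold(pos, neg))


class TestBackground:
    def test_sample_inside_mask_and_seeded(self, tiny_grid):
        mask = np.zeros(tiny_grid.shape, dtype=bool)
        mask[5:10, 5:10] = True
        a = sdm.sample_background(mask, tiny_grid, n=200, seed=3)
        b = sdm.sample_background(mask, tiny_grid, n=200, seed=3)
        assert len(a) == 200
        assert a["row"].between(5, 9).all() and a["col"].between(5, 9).all()
        pd.testing.assert_frame_equal(a, b)

    def test_empty_mask_rejected(self, tiny_grid):
        with pytest.raises(ValueError):
            sdm.sample_background(np.zeros(tiny_grid.shape, bool), tiny_grid)


class TestFeatures:
    def test_standardized_linear_and_quadratic(self):
        bg = pd.DataFrame({"x": [0.0, 2.0]})  # mean 1, sd 1
        std = sdm.fit_standardization(bg, ["x"])
        X = sdm.build_features(pd.DataFrame({"x": [1.0, 2.0]}), std)
        np.testing.assert_allclose(X, [[0.0, 0.0], [1.0, 1.0]])

    def test_constant_predictor_dropped_with_warning(self):
        bg = pd.DataFrame({"x": [1.0, 2.0], "c": [5.0, 5.0]})
        with pytest.warns(UserWarning, match="constant"):
            std = sdm.fit_standardization(bg, ["x", "c"])
        assert std.predictors == ["x"]
        assert sdm.build_features(bg, std).shape[1] == 2

    def test_missing_values_rejected(self):
        bg = pd.DataFrame({"x": [1.0, 2.0]})
        std = sdm.fit_standardization(bg, ["x"])
        with pytest.raises(ValueError, match="missing"):
            sdm.build_features(pd.DataFrame({"x": [np.nan]}), std)


class TestFit:
    def test_separable_predictor_gets_positive_coefficient(self):
        rng = np.random.default_rng(0)
        pres = pd.DataFrame({"x": rng.normal(2.0, 0.3, 100)})
        bg = pd.DataFrame({"x": rng.normal(-2.0, 0.3, 200)})
        model = sdm.fit_model(pres, bg, ["x"], lam=1.0)
        assert model.coefficients[0] > 0

    def test_huge_ridge_shrinks_to_prevalence(self):
        rng = np.random.default_rng(1)
        pres = pd.DataFrame({"x": rng.normal(1.0, 1.0, 50)})
        bg = pd.DataFrame({"x": rng.normal(0.0, 1.0, 150)})
        model = sdm.fit_model(pres, bg, ["x"], lam=1e6)
        assert np.abs(model.coefficients).max() < 1e-3
        scores = model.score_raw(bg)
        assert scores.std() < 1e-3
        assert scores.mean() == pytest.approx(0.25, abs=0.01)

    def test_row_order_and_affine_rescaling_invariance(self):
        rng = np.random.default_rng(2)
        pres = pd.DataFrame({"x": rng.normal(1, 1, 60), "y": rng.normal(0, 1, 60)})
        bg = pd.DataFrame({"x": rng.normal(0, 1, 120), "y": rng.normal(0, 1, 120)})
        m1 = sdm.fit_model(pres, bg, ["x", "y"], lam=1.0)
        shuffled = bg.sample(frac=1.0, random_state=5)
        scaled_pres = pres.assign(x=pres["x"] * 10 + 3)
        scaled_bg = shuffled.assign(x=shuffled["x"] * 10 + 3)
        m2 = sdm.fit_model(scaled_pres, scaled_bg, ["x", "y"], lam=1.0)
        np.testing.assert_allclose(m1.coefficients, m2.coefficients, atol=1e-6)
        assert m1.intercept == pytest.approx(m2.intercept, abs=1e-6)

    def test_recovers_gaussian_niche_optimum(self):
        # a quadratic-logistic fit to presences drawn from a Gaussian
        # niche should put its bio1 optimum near the true one
        grid = build_grid(0, 4, -2, 2, 0.05)
        rng = np.random.default_rng(3)
        env = EnvStack(grid, {
            "bio1": rng.uniform(5, 25, grid.shape),
            "bio12": rng.uniform(500, 1500, grid.shape),
        })
        errs = []
        for seed in range(20):
            muT = 10.0 + 8.0 * (seed / 19)
            from montrange.dispersal import SpeciesTraits
            tr = SpeciesTraits("herb", frozenset({"animal"}))
            vs, occ = simulate_species(env, "v", (muT, 1000.0), (1.0, 300.0), 0.3,
                                       tr, n_presence=200, seed=seed)
            row, col = grid.points_to_cells(occ["decimalLongitude"].to_numpy(),
                                            occ["decimalLatitude"].to_numpy())
            pres = pd.DataFrame({p: env.layers[p][row, col] for p in ("bio1", "bio12")})
            bg_pts = sdm.sample_background(np.ones(grid.shape, bool), grid, 1000, seed)
            bg = pd.DataFrame({p: env.layers[p][bg_pts["row"], bg_pts["col"]]
                               for p in ("bio1", "bio12")})
            model = sdm.fit_model(pres, bg, ["bio1", "bio12"], lam=1.0)
            opt = sdm.marginal_optimum(model, "bio1", env.layers["bio1"].ravel())
            errs.append(abs(opt - muT))
        assert np.median(errs) <= 0.5


class TestPredict:
    def test_constant_environment_constant_raster(self, tiny_grid):
        bg = pd.DataFrame({"x": [0.0, 1.0, 2.0]})
        model = sdm.fit_model(pd.DataFrame({"x": [1.5, 2.0]}), bg, ["x"], lam=1.0)
        env = EnvStack(tiny_grid, {"x": np.full(tiny_grid.shape, 1.0)})
        out = sdm.predict(model, env)
        assert np.unique(out).size == 1

    def test_prediction_matches_training_score(self, tiny_grid):
        rng = np.random.default_rng(4)
        field = rng.uniform(0, 10, tiny_grid.shape)
        env = EnvStack(tiny_grid, {"x": field})
        pres = pd.DataFrame({"x": field[2, 2:5]})
        bg = pd.DataFrame({"x": field.ravel()[::7]})
        model = sdm.fit_model(pres, bg, ["x"], lam=1.0)
        out = sdm.predict(model, env)
        np.testing.assert_allclose(out[2, 2:5], model.score_raw(pres), rtol=1e-12)

    def test_mask_yields_missing_outside(self, tiny_grid):
        bg = pd.DataFrame({"x": [0.0, 1.0]})
        model = sdm.fit_model(pd.DataFrame({"x": [1.0]}), bg, ["x"], lam=1.0)
        env = EnvStack(tiny_grid, {"x": np.zeros(tiny_grid.shape)})
        mask = np.zeros(tiny_grid.shape, bool)
        mask[0, 0] = True
        out = sdm.predict(model, env, mask)
        assert np.isfinite(out[0, 0]) and np.isnan(out[1:, :]).all()

    def test_missing_layer_rejected(self, tiny_grid):
        bg = pd.DataFrame({"x": [0.0, 1.0]})
        model = sdm.fit_model(pd.DataFrame({"x": [1.0]}), bg, ["x"], lam=1.0)
        env = EnvStack(tiny_grid, {"y": np.zeros(tiny_grid.shape)})
        with pytest.raises(ValueError, match="lacks"):
            sdm.predict(model, env)


class TestBlocks:
    def test_default_k_folds_and_cohabitation(self, small_grid):
        rng = np.random.default_rng(5)
        lon = rng.uniform(20, 30, 400)
        lat = rng.uniform(-35, -25, 400)
        pres = rng.random(400) < 0.3
        blocks = sdm.assign_blocks(lon, lat, pres, small_grid, 250.0, k=5, seed=0)
        assert np.unique(blocks.fold_id).size == 5
        # nearby points share block and fold
        same = sdm.assign_blocks(np.concatenate([lon, [25.0, 25.005]]),
                                 np.concatenate([lat, [-30.0, -30.005]]),
                                 np.concatenate([pres, [True, True]]),
                                 small_grid, 250.0, k=5, seed=0)
        assert same.block_id[-1] == same.block_id[-2]
        assert same.fold_id[-1] == same.fold_id[-2]

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_greedy_balance_bound(self, seed):
        grid = build_grid(20, 30, -35, -25, 0.05)
        rng = np.random.default_rng(seed)
        n = int(rng.integers(100, 400))
        lon = rng.uniform(20, 30, n)
        lat = rng.uniform(-35, -25, n)
        pres = rng.random(n) < rng.uniform(0.1, 0.9)
        try:
            blocks = sdm.assign_blocks(lon, lat, pres, grid, 250.0, k=4, seed=seed)
        except ValueError:
            return  # fewer non-empty blocks than folds
        totals = np.bincount(blocks.fold_id, weights=pres.astype(float), minlength=4)
        per_block = pd.DataFrame({"b": blocks.block_id, "p": pres}).groupby("b")["p"].sum()
        assert totals.max() - totals.min() <= max(per_block.max(), 0)

    def test_too_few_blocks_rejected(self, small_grid):
        with pytest.raises(ValueError, match="blocks"):
            sdm.assign_blocks(np.array([25.0]), np.array([-30.0]), np.array([True]),
                              small_grid, 250.0, k=5, seed=0)


class TestCrossValidation:
    def _data(self, seed=0, informative=True):
        rng = np.random.default_rng(seed)
        n_p, n_b = 80, 400
        if informative:
            pres = pd.DataFrame({"x": rng.normal(2, 0.5, n_p)})
            bg = pd.DataFrame({"x": rng.normal(0, 1, n_b)})
        else:
            pres = pd.DataFrame({"x": rng.normal(0, 1, n_p)})
            bg = pd.DataFrame({"x": rng.normal(0, 1, n_b)})
        fold_p = rng.integers(0, 5, n_p)
        fold_b = rng.integers(0, 5, n_b)
        return pres, bg, fold_p, fold_b

    def test_informative_predictor_accepted(self):
        pres, bg, fp, fb = self._data(0, True)
        aucs, mean, accepted = sdm.cross_validate(pres, bg, ["x"], fp, fb)
        assert len(aucs) == 5
        assert mean > 0.9 and accepted

    def test_gate_is_inclusive_at_070(self):
        # acceptance is mean >= auc_min, checked at the boundary
        pres, bg, fp, fb = self._data(1, True)
        _, mean, accepted = sdm.cross_validate(pres, bg, ["x"], fp, fb, auc_min=0.70)
        assert accepted == (mean >= 0.70)
        # a gate just above the achieved mean flips the decision
        _, _, rejected = sdm.cross_validate(pres, bg, ["x"], fp, fb, auc_min=mean + 1e-9)
        assert not rejected

    def test_null_labels_give_chance_auc(self):
        means = []
        for seed in range(20):
            pres, bg, fp, fb = self._data(seed, informative=False)
            _, mean, _ = sdm.cross_validate(pres, bg, ["x"], fp, fb)
            means.append(mean)
        assert 0.4 <= np.mean(means) <= 0.6

    def test_degenerate_fold_skipped(self):
        pres, bg, fp, fb = self._data(2, True)
        fp[fp == 0] = 1  # fold 0 has no presences
        with pytest.warns(UserWarning, match="skipped"):
            aucs, _, _ = sdm.cross_validate(pres, bg, ["x"], fp, fb)
        assert len(aucs) == 4


class TestPermutationImportance:
    def test_single_informative_predictor_dominates(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            pres = pd.DataFrame({"x": rng.normal(2, 0.5, 80), "junk": rng.normal(0, 1, 80)})
            bg = pd.DataFrame({"x": rng.normal(0, 1, 300), "junk": rng.normal(0, 1, 300)})
            model = sdm.fit_model(pres, bg, ["x", "junk"], lam=1.0)
            imp = sdm.permutation_importance(model, pres, bg, n_perm=5, seed=seed)
            hits += imp["x"] > 0.9
        assert hits >= 19

    def test_seeded_determinism(self):
        rng = np.random.default_rng(0)
        pres = pd.DataFrame({"x": rng.normal(1, 1, 40)})
        bg = pd.DataFrame({"x": rng.normal(0, 1, 100)})
        model = sdm.fit_model(pres, bg, ["x"], lam=1.0)
        a = sdm.permutation_importance(model, pres, bg, n_perm=5, seed=7)
        b = sdm.permutation_importance(model, pres, bg, n_perm=5, seed=7)
        assert a == b
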