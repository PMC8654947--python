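"""Compatibility model: redundancy reduction, forest, ALE, H-statistic."""

import numpy as np
import pandas as pd
import pytest

import dipscan as d


def _benchmark(n, seed=0, noise_sd=0.0):
    """Fitness from four named generating features plus nuisance noise
    features; hydrophobicity x motif length is the planted interaction."""
    rng = np.random.default_rng(seed)
    X = pd.DataFrame({k: rng.normal(0, 1, n) for k in
                      ["stiffness", "contact_density", "hydrophobicity",
                       "motif_length", "noise_a", "noise_b", "noise_c",
                       "noise_d"]})
    y = (-1.5 * X["stiffness"] + 1.0 * X["contact_density"]
         + 0.8 * X["hydrophobicity"] * X["motif_length"]
         + 0.6 * X["motif_length"])
    if noise_sd:
        y = y + rng.normal(0, noise_sd, n)
    return X, y


class TestReduceRedundancy:
    def test_duplicate_keeps_exactly_one(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"f1": rng.normal(0, 1, 100)})
        X["f2"] = X["f1"]
        X["f3"] = rng.normal(0, 1, 100)
        y = X["f1"] + 0.1 * rng.normal(0, 1, 100)
        fs = d.reduce_redundancy(X, y)
        assert sum(f in fs.retained for f in ("f1", "f2")) == 1
        assert "f3" in fs.retained

    def test_uncorrelated_features_all_retained(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(0, 1, (200, 3)),
                         columns=["a", "b", "c"])
        fs = d.reduce_redundancy(X, rng.normal(0, 1, 200))
        assert sorted(fs.retained) == ["a", "b", "c"]

    def test_representative_maximizes_response_correlation(self):
        rng = np.random.default_rng(2)
        z = rng.normal(0, 1, 300)
        y = z + rng.normal(0, 0.1, 300)
        X = pd.DataFrame({
            "strong": z,                       # high response correlation
            "weak": z + rng.normal(0, 0.0, 300),  # identical copy
            "indep": rng.normal(0, 1, 300)})
        # make 'weak' a slightly noisier copy so 'strong' wins
        X["weak"] = z + rng.normal(0, 0.3, 300)
        fs = d.reduce_redundancy(X, y)
        assert "strong" in fs.retained
        assert "weak" not in fs.retained
        assert "indep" in fs.retained

    def test_idempotent(self):
        X, y = _benchmark(300, seed=3)
        X["dup"] = X["stiffness"]
        fs = d.reduce_redundancy(X, y)
        fs2 = d.reduce_redundancy(X[fs.retained], y)
        assert fs2.retained == fs.retained
        assert fs2.groups == []

    def test_constant_feature_removed_first(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame({"a": rng.normal(0, 1, 100),
                          "const": np.ones(100),
                          "b": rng.normal(0, 1, 100)})
        fs = d.reduce_redundancy(X, rng.normal(0, 1, 100))
        assert fs.dropped_constant == ["const"]
        assert "const" not in fs.retained

    def test_grouped_response_scoring(self):
        # response correlation summed within row groups (e.g. positions)
        rng = np.random.default_rng(5)
        groups = np.repeat(np.arange(10), 30)
        z = rng.normal(0, 1, 300)
        y = np.concatenate([(1 if g % 2 else -1) * z[groups == g]
                            for g in range(10)])
        X = pd.DataFrame({"f": z, "f_copy": z + rng.normal(0, 0.2, 300),
                          "other": rng.normal(0, 1, 300)})
        fs = d.reduce_redundancy(X, y, row_groups=groups)
        # per-group |rho| is high for f even though global rho ~ 0
        assert "f" in fs.retained


class TestCompatibilityForest:
    def test_same_seed_gives_identical_split(self):
        X, y = _benchmark(300, seed=0)
        a = d.CompatibilityForest(n_trees=50, random_state=3).fit(X, y)
        b = d.CompatibilityForest(n_trees=50, random_state=3).fit(X, y)
        np.testing.assert_array_equal(a.train_idx_, b.train_idx_)
        np.testing.assert_array_equal(a.test_idx_, b.test_idx_)

    def test_split_disjoint_and_exhaustive(self):
        X, y = _benchmark(200, seed=1)
        cf = d.CompatibilityForest(n_trees=20, random_state=0).fit(X, y)
        joined = np.concatenate([cf.train_idx_, cf.test_idx_])
        assert len(joined) == 200
        assert len(np.unique(joined)) == 200

    def test_learnable_function_high_variance_explained(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"x1": rng.uniform(-1, 1, 2000),
                          "x2": rng.uniform(-1, 1, 2000)})
        y = 2.0 * X["x1"] - 1.0 * X["x2"]
        cf = d.CompatibilityForest(n_trees=300, random_state=0).fit(X, y)
        assert cf.heldout_variance_explained_ >= 0.9

    def test_pure_noise_low_variance_explained(self):
        ves = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.normal(0, 1, (400, 4)),
                             columns=list("abcd"))
            y = rng.normal(0, 1, 400)
            cf = d.CompatibilityForest(n_trees=100,
                                       random_state=seed).fit(X, y)
            ves.append(cf.heldout_variance_explained_)
        assert np.median(ves) <= 0.1

    def test_constant_response_rejected(self):
        X, _ = _benchmark(100)
        with pytest.raises(ValueError, match="constant"):
            d.CompatibilityForest().fit(X, np.ones(100))

    def test_too_few_rows_rejected(self):
        X, y = _benchmark(30)
        with pytest.raises(ValueError, match="complete-case"):
            d.CompatibilityForest().fit(X, y)


class TestDropImportance:
    def test_generating_features_rank_above_noise(self):
        X, y = _benchmark(1500, seed=0, noise_sd=0.3)
        imp = d.drop_importance(X, y, n_trees=150, random_state=0)
        top4 = set(imp.index[:4])
        assert top4 == {"stiffness", "contact_density", "hydrophobicity",
                        "motif_length"}

    def test_noise_feature_importance_near_zero(self):
        X, y = _benchmark(1500, seed=1, noise_sd=0.3)
        imp = d.drop_importance(X, y, n_trees=150, random_state=0)
        noise = imp.loc[["noise_a", "noise_b", "noise_c", "noise_d"],
                        "mae_increase_raw"]
        signal = imp.loc["stiffness", "mae_increase_raw"]
        assert noise.abs().max() < 0.2 * signal
        assert (imp["mae_increase"] >= 0).all()

    def test_duplicated_feature_masks_importance(self):
        X, y = _benchmark(1200, seed=2, noise_sd=0.3)
        single = d.drop_importance(X[["stiffness", "contact_density",
                                      "motif_length", "hydrophobicity"]],
                                   y, n_trees=150, random_state=0)
        X2 = X[["stiffness", "contact_density", "motif_length",
                "hydrophobicity"]].copy()
        X2["stiffness_dup"] = X2["stiffness"] \
            + np.random.default_rng(0).normal(0, 0.05, len(X2))
        dup = d.drop_importance(X2, y, n_trees=150, random_state=0)
        assert dup.loc["stiffness", "mae_increase_raw"] \
            < single.loc["stiffness", "mae_increase_raw"]

    def test_single_feature_rejected(self):
        X, y = _benchmark(200)
        with pytest.raises(ValueError):
            d.drop_importance(X[["stiffness"]], y)


class TestALE:
    def test_linear_oracle_slope(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"x1": rng.uniform(-1, 1, 3000),
                          "x2": rng.normal(0, 1, 3000)})
        prof = d.ale_first_order(lambda df: 2.0 * df["x1"].to_numpy(),
                                 X, "x1", n_bins=20)
        slope = np.polyfit(prof.edges[0], prof.effects, 1)[0]
        assert slope == pytest.approx(2.0, rel=0.1)
        assert np.average(
            (prof.effects[:-1] + prof.effects[1:]) / 2) == pytest.approx(
                0.0, abs=0.2)

    def test_irrelevant_feature_flat_zero(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"x1": rng.uniform(-1, 1, 1000),
                          "x2": rng.normal(0, 1, 1000)})
        prof = d.ale_first_order(lambda df: 3.0 * df["x1"].to_numpy(),
                                 X, "x2")
        assert np.abs(prof.effects).max() < 1e-10

    def test_constant_shift_invariance(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"x1": rng.uniform(-1, 1, 800),
                          "x2": rng.normal(0, 1, 800)})
        f = lambda df: np.sin(2 * df["x1"].to_numpy())
        g = lambda df: np.sin(2 * df["x1"].to_numpy()) + 17.0
        a = d.ale_first_order(f, X, "x1")
        b = d.ale_first_order(g, X, "x1")
        np.testing.assert_allclose(a.effects, b.effects, atol=1e-10)

    def test_constant_feature_warns_flat(self):
        X = pd.DataFrame({"x1": np.ones(100), "x2": np.arange(100.0)})
        with pytest.warns(UserWarning, match="constant"):
            prof = d.ale_first_order(lambda df: df["x2"].to_numpy(),
                                     X, "x1")
        assert (prof.effects == 0).all()

    def test_additive_function_zero_second_order(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame({"x1": rng.uniform(-1, 1, 3000),
                          "x2": rng.uniform(-1, 1, 3000)})
        f = lambda df: np.sin(df["x1"].to_numpy()) + df["x2"].to_numpy() ** 2
        prof = d.ale_second_order(f, X, "x1", "x2", n_bins=8)
        assert np.abs(prof.effects).max() < 0.05 * np.std(f(X))

    def test_multiplicative_saddle_corner_signs(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame({"x1": rng.uniform(-1, 1, 4000),
                          "x2": rng.uniform(-1, 1, 4000)})
        f = lambda df: df["x1"].to_numpy() * df["x2"].to_numpy()
        prof = d.ale_second_order(f, X, "x1", "x2", n_bins=10)
        eff = prof.effects
        assert eff[0, 0] > 0 and eff[-1, -1] > 0
        assert eff[0, -1] < 0 and eff[-1, 0] < 0

    def test_second_order_symmetric_in_arguments(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame({"x1": rng.uniform(-1, 1, 2000),
                          "x2": rng.uniform(-1, 1, 2000)})
        f = lambda df: df["x1"].to_numpy() * df["x2"].to_numpy()
        a = d.ale_second_order(f, X, "x1", "x2", n_bins=6)
        b = d.ale_second_order(f, X, "x2", "x1", n_bins=6)
        np.testing.assert_allclose(a.effects, b.effects.T, atol=1e-10)

    def test_estimator_converges_with_resolution(self):
        # first-order ALE of a linear function approaches the exact line
        rng = np.random.default_rng(6)
        X = pd.DataFrame({"x1": rng.uniform(-1, 1, 5000),
                          "x2": rng.normal(0, 1, 5000)})
        f = lambda df: 2.0 * df["x1"].to_numpy()
        errs = []
        for bins in (5, 40):
            prof = d.ale_first_order(f, X, "x1", n_bins=bins)
            exact = 2.0 * (prof.edges[0] - np.mean(X["x1"]))
            errs.append(np.max(np.abs(prof.effects - exact)))
        assert errs[1] < errs[0]


class TestInteractionStrength:
    def test_additive_oracle_near_zero(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"x1": rng.uniform(-1, 1, 1500),
                          "x2": rng.uniform(-1, 1, 1500)})
        f = lambda df: df["x1"].to_numpy() + 2 * df["x2"].to_numpy()
        out = d.interaction_strength(f, X, n_sample=250, random_state=0)
        assert out["h"].iloc[0] < 0.05

    def test_multiplicative_oracle_near_one(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"x1": rng.uniform(-1, 1, 1500),
                          "x2": rng.uniform(-1, 1, 1500)})
        f = lambda df: df["x1"].to_numpy() * df["x2"].to_numpy()
        out = d.interaction_strength(f, X, n_sample=250, random_state=0)
        assert out["h"].iloc[0] == pytest.approx(1.0, abs=0.1)

    def test_affine_response_invariance(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"x1": rng.uniform(-1, 1, 800),
                          "x2": rng.uniform(-1, 1, 800)})
        f = lambda df: df["x1"].to_numpy() * df["x2"].to_numpy() \
            + 0.5 * df["x1"].to_numpy()
        g = lambda df: 7.0 * f(df) - 3.0
        hf = d.interaction_strength(f, X, n_sample=200,
                                    random_state=0)["h"].iloc[0]
        hg = d.interaction_strength(g, X, n_sample=200,
                                    random_state=0)["h"].iloc[0]
        assert hf == pytest.approx(hg, abs=1e-10)

    def test_planted_interacting_pair_dominates(self):
        X, y = _benchmark(1200, seed=3, noise_sd=0.3)
        cols = ["stiffness", "contact_density", "hydrophobicity",
                "motif_length"]
        cf = d.CompatibilityForest(n_trees=150, random_state=0).fit(
            X[cols], y)
        out = d.interaction_strength(cf, X[cols], n_sample=120,
                                     random_state=0)
        out = out.set_index(["feature_a", "feature_b"])
        planted = out.loc[("hydrophobicity", "motif_length"), "h"]
        others = out.drop(index=("hydrophobicity", "motif_length"))["h"]
        assert planted > others.max()
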