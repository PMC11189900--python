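"""Predictor tests: splits, CNN training contracts, linear-model
parameter recovery, k-mer oracle support recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from utrforge.predictors import (
    CNNSpec,
    ConvNetResults,
    ConvolutionalMRLRegression,
    KmerFilterSpec,
    KmerOracleRegression,
    PositionalTrimerRegression,
    evaluate_r2,
    make_split,
)
from utrforge.seqcore import kmer_feature_names, kmer_log_features
from utrforge.synthetic import generate_library


def random_table(n, rng, length=25):
    seqs = ["".join("ACGT"[c] for c in rng.integers(0, 4, length)) for _ in range(n)]
    return pd.DataFrame({
        "sequence": seqs,
        "mrl": rng.uniform(1, 8, n),
        "reads": rng.integers(50, 5000, n),
    }, index=[f"v{i:05d}" for i in range(n)])


class TestMakeSplit:
    def test_sizes(self):
        table = random_table(10, np.random.default_rng(0))
        split = make_split(table, k_test=2, k_val=2)
        assert len(split.test) == 2 and len(split.validation) == 2 and len(split.train) == 6

    def test_tie_break_by_id_is_stable(self):
        table = random_table(10, np.random.default_rng(1))
        table["reads"] = 100  # all tied
        a = make_split(table, 3, 3)
        b = make_split(table.sample(frac=1, random_state=7), 3, 3)
        assert list(a.test.index) == sorted(table.index)[:3]
        assert list(a.test.index) == list(b.test.index)

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(2)
        table = random_table(10_000, rng)
        split = make_split(table, 2000, 2000)
        order = sorted(table.index, key=lambda v: (-table.loc[v, "reads"], v))
        assert list(split.test.index) == order[:2000]
        assert list(split.validation.index) == order[2000:4000]
        assert set(split.train.index) == set(order[4000:])

    def test_too_small_errors(self):
        with pytest.raises(ValueError, match="need more"):
            make_split(random_table(10, np.random.default_rng(3)), 5, 5)


class TestCNN:
    def test_spec_range_validation(self):
        with pytest.raises(ValueError):
            CNNSpec(n_blocks=6)
        with pytest.raises(ValueError):
            CNNSpec(kernel_size=8)
        with pytest.raises(ValueError):
            CNNSpec(base_filters=8)

    def test_block_filter_doubling(self):
        spec = CNNSpec(n_blocks=3, base_filters=16)
        assert [spec.block_filters(b) for b in (1, 2, 3)] == [16, 32, 64]

    def test_architecture_family_shapes(self):
        # two conv layers per block, pool stride 2, doubling filters,
        # dense head with a single linear output
        rng = np.random.default_rng(0)
        recs = generate_library(40, seed=1)
        seqs = [r.sequence for r in recs]
        y = rng.normal(4, 1, 40)
        res = ConvolutionalMRLRegression(
            seqs[:30], y[:30], seqs[30:], y[30:],
            spec=CNNSpec(n_blocks=2, base_filters=16, kernel_size=5, dense_units=10),
        ).fit(max_epochs=1, seed=0)
        shapes = dict(res.layer_shapes())
        assert shapes["block1_conv1"] == (5 * 4, 16)
        assert shapes["block1_conv2"] == (5 * 16, 16)
        assert shapes["block2_conv1"] == (5 * 16, 32)
        assert shapes["block2_conv2"] == (5 * 32, 32)
        assert shapes["block1_pool"] == (2,)
        # 25 -> pool 12 -> pool 6; flatten 6*32 -> dense 10 -> 1
        assert shapes["dense"] == (6 * 32, 10)
        assert shapes["output"] == (10, 1)

    def test_constant_target_convergence(self):
        rng = np.random.default_rng(1)
        recs = generate_library(300, seed=2)
        seqs = [r.sequence for r in recs]
        y = np.full(300, 4.2)
        res = ConvolutionalMRLRegression(
            seqs[:250], y[:250], seqs[250:], y[250:],
            spec=CNNSpec(n_blocks=1, base_filters=16, dense_units=10,
                         conv_dropout=0.0, dense_dropout=0.0),
        ).fit(max_epochs=80, patience=80, lr=1e-2, batch_size=32, seed=0)
        assert res.best_val_mse < 1e-2

    def test_training_is_bitwise_deterministic(self):
        rng = np.random.default_rng(3)
        recs = generate_library(120, seed=4)
        seqs = [r.sequence for r in recs]
        y = rng.normal(4, 1, 120)
        kwargs = dict(max_epochs=3, patience=3, seed=11)
        model = lambda: ConvolutionalMRLRegression(
            seqs[:100], y[:100], seqs[100:], y[100:],
            spec=CNNSpec(n_blocks=1, base_filters=16, dense_units=10))
        h1 = model().fit(**kwargs).history
        h2 = model().fit(**kwargs).history
        assert (h1["train_mse"].to_numpy() == h2["train_mse"].to_numpy()).all()
        assert (h1["val_mse"].to_numpy() == h2["val_mse"].to_numpy()).all()

    def test_predict_order_and_batching(self):
        rng = np.random.default_rng(5)
        recs = generate_library(60, seed=6)
        seqs = [r.sequence for r in recs]
        y = rng.normal(4, 1, 60)
        res = ConvolutionalMRLRegression(
            seqs[:50], y[:50], seqs[50:], y[50:],
            spec=CNNSpec(n_blocks=1, base_filters=16, dense_units=10),
        ).fit(max_epochs=1, seed=0)
        batch = res.predict(seqs[:8])
        perm = [3, 1, 4, 1, 5]
        np.testing.assert_allclose(res.predict([seqs[i] for i in perm]),
                                   batch[perm], atol=1e-12)
        np.testing.assert_allclose(res.predict([seqs[0]]), batch[:1], atol=1e-12)

    def test_checkpoint_round_trip(self, tmp_path):
        rng = np.random.default_rng(6)
        recs = generate_library(60, seed=7)
        seqs = [r.sequence for r in recs]
        y = rng.normal(4, 1, 60)
        res = ConvolutionalMRLRegression(
            seqs[:50], y[:50], seqs[50:], y[50:],
            spec=CNNSpec(n_blocks=1, base_filters=16, dense_units=10),
        ).fit(max_epochs=2, seed=0)
        path = tmp_path / "model.npz"
        res.save(path)
        loaded = ConvNetResults.load(path)
        np.testing.assert_allclose(loaded.predict(seqs[:5]), res.predict(seqs[:5]),
                                   atol=1e-12)


class TestRandomSearch:
    def test_trials_sorted_and_within_ranges(self):
        from utrforge.predictors import random_search_cnn

        rng = np.random.default_rng(30)
        table = random_table(80, rng)
        split = make_split(table, k_test=10, k_val=10)
        trials = random_search_cnn(split, n_trials=2, seed=0,
                                   fit_kwargs=dict(max_epochs=1))
        assert (np.diff(trials["val_mse"]) >= 0).all()
        for spec in trials["spec"]:
            assert 1 <= spec.n_blocks <= 5 and 2 <= spec.kernel_size <= 7


class TestPositionalTrimer:
    def test_zero_targets_zero_weights(self):
        recs = generate_library(200, seed=1)
        fit = PositionalTrimerRegression([r.sequence for r in recs],
                                         np.zeros(200)).fit()
        assert np.abs(fit.weights).max() < 1e-8

    def test_planted_weight_recovery(self):
        # targets from a planted positional 3-mer linear model + noise;
        # overlapping-window indicators make raw weights identifiable only
        # up to reparameterization, so the reference is the identifiable
        # (noise-free least-squares) representation of the planted model
        rng = np.random.default_rng(2)
        n, L = 20_000, 25
        recs = generate_library(n, seed=3)
        seqs = [r.sequence for r in recs]
        planted = rng.normal(0, 0.2, size=(L - 2, 64))
        from utrforge.seqcore import positional_3mer_features

        X = positional_3mer_features(seqs)
        y0 = X @ planted.ravel()
        identifiable = PositionalTrimerRegression(seqs, y0).fit().weights
        y = y0 + rng.normal(0, 0.1, n)
        fit = PositionalTrimerRegression(seqs, y).fit()
        r = stats.pearsonr(fit.weights.ravel(), identifiable.ravel())[0]
        assert r >= 0.95

    def test_replicate_discrimination(self):
        rng = np.random.default_rng(4)
        n, L = 8000, 25
        planted = rng.normal(0, 0.2, size=(L - 2, 64))
        other = rng.normal(0, 0.2, size=(L - 2, 64))
        from utrforge.seqcore import positional_3mer_features

        def rep(seed, weights):
            recs = generate_library(n, seed=seed)
            X = positional_3mer_features([r.sequence for r in recs])
            y = X @ weights.ravel() + np.random.default_rng(seed + 50).normal(0, 0.1, n)
            return PositionalTrimerRegression([r.sequence for r in recs], y).fit()

        a, b = rep(10, planted), rep(11, planted)
        c = rep(12, other)
        assert a.weight_correlation(b) > a.weight_correlation(c)

    def test_permuted_targets_no_recovery(self):
        rng = np.random.default_rng(5)
        n = 5000
        recs = generate_library(n, seed=6)
        planted = rng.normal(0, 0.2, size=(23, 64))
        from utrforge.seqcore import positional_3mer_features

        X = positional_3mer_features([r.sequence for r in recs])
        y = X @ planted.ravel() + rng.normal(0, 0.1, n)
        fit = PositionalTrimerRegression([r.sequence for r in recs],
                                         rng.permutation(y)).fit()
        r = stats.pearsonr(fit.weights.ravel(), planted.ravel())[0]
        assert abs(r) < 0.1

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="one length"):
            PositionalTrimerRegression(["ACGTA", "ACGT"], [1, 2])


class TestKmerOracle:
    def test_initial_ug_and_uaug_filters(self):
        table = pd.DataFrame({
            "sequence": ["TG" + "C" * 23, "CC" + "C" * 23, "CCATG" + "C" * 20],
            "mrl": [4.0, 4.0, 4.0],
            "reads": [300, 300, 300],
        }, index=["ug", "clean", "uaug"])
        kept = KmerOracleRegression.apply_filters(table, KmerFilterSpec())
        assert list(kept.index) == ["clean"]

    def test_read_depth_filter(self):
        table = pd.DataFrame({
            "sequence": ["C" * 25, "G" * 25],
            "mrl": [4.0, 4.0],
            "reads": [249, 250],
        }, index=["low", "ok"])
        kept = KmerOracleRegression.apply_filters(table, KmerFilterSpec())
        assert list(kept.index) == ["ok"]

    def test_huge_alpha_empty_support_errors(self):
        rng = np.random.default_rng(7)
        table = random_table(300, rng)
        table["reads"] = 300
        model = KmerOracleRegression(table, KmerFilterSpec(exclude_uaug=False,
                                                           exclude_initial_ug=False))
        with pytest.raises(ValueError, match="no features"):
            model.fit(lasso_alpha=1e6, n_train_subset=300)

    def test_support_shrinks_with_alpha(self):
        rng = np.random.default_rng(8)
        table = random_table(500, rng)
        table["reads"] = 300
        model = KmerOracleRegression(table, KmerFilterSpec(exclude_uaug=False,
                                                           exclude_initial_ug=False),
                                     k_min=2, k_max=3)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            small = model.fit(lasso_alpha=0.001, n_train_subset=500)
            large = model.fit(lasso_alpha=0.01, n_train_subset=500)
        assert len(large.selected_features) <= len(small.selected_features)

    def test_planted_sparse_support_recovery(self):
        # 10 planted k-mer effects; Lasso support should cover them and the
        # unpenalized refit should land within 10% of the planted weights
        rng = np.random.default_rng(9)
        n = 12_000
        recs = generate_library(n, seed=10)
        seqs = [r.sequence for r in recs]
        names = kmer_feature_names(2, 6)
        planted_idx = rng.choice(len(names), size=10, replace=False)
        planted_w = rng.uniform(0.5, 1.5, 10) * rng.choice([-1, 1], 10)
        X = kmer_log_features(seqs, 2, 6)
        y = 4.0 + X[:, planted_idx] @ planted_w + rng.normal(0, 0.1, n)
        table = pd.DataFrame({"sequence": seqs, "mrl": y, "reads": 300},
                             index=[r.id for r in recs])
        model = KmerOracleRegression(table, KmerFilterSpec(exclude_uaug=False,
                                                           exclude_initial_ug=False))
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = model.fit(lasso_alpha=0.001, n_train_subset=n, seed=0)
        support = set(fit.support.tolist())
        assert set(planted_idx.tolist()) <= support
        refit = dict(zip(fit.support.tolist(), fit.weights))
        for idx, w in zip(planted_idx.tolist(), planted_w):
            assert refit[idx] == pytest.approx(w, rel=0.10)

    def test_pipeline_deterministic_given_seed(self):
        rng = np.random.default_rng(11)
        table = random_table(400, rng)
        table["reads"] = 300
        model = KmerOracleRegression(table, KmerFilterSpec(exclude_uaug=False,
                                                           exclude_initial_ug=False),
                                     k_min=2, k_max=3)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = model.fit(lasso_alpha=0.005, n_train_subset=200, seed=5)
            b = model.fit(lasso_alpha=0.005, n_train_subset=200, seed=5)
        assert a.selected_features == b.selected_features
        np.testing.assert_array_equal(a.weights, b.weights)


class TestEvaluateR2:
    def test_perfect_and_sign_blind(self):
        x = np.array([1.0, 2, 3, 4])
        assert evaluate_r2(x, x) == pytest.approx(1.0)
        assert evaluate_r2(-x, x) == pytest.approx(1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            a, b = rng.normal(size=50), rng.normal(size=50)
            cov = np.mean((a - a.mean()) * (b - b.mean()))
            expected = cov**2 / (a.var() * b.var())
            assert evaluate_r2(a, b) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            evaluate_r2([1, 1, 1], [1, 2, 3])
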