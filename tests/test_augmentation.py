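import numpy as np
import pandas as pd
import pytest

import omixaug as oa
from omixaug.augmentation import corrupt_windows

FAST_GAN = dict(hidden_units=8, epochs=2, batch_size=64)


def _table(counts, n_genes=4, seed=0):
    """A small training table (expression + stages) with given stage counts."""
    rng = np.random.default_rng(seed)
    y = np.repeat(np.arange(1, len(counts) + 1), counts)
    ids = pd.Index([f"s{i}" for i in range(len(y))])
    X = pd.DataFrame(rng.normal(size=(len(y), n_genes)), index=ids,
                     columns=[f"g{j}" for j in range(n_genes)])
    return X, pd.Series(y, index=ids)


class TestGan:
    def test_single_sample_stage_rejected(self):
        X, _ = _table([1], n_genes=3)
        with pytest.raises(ValueError, match="single sample"):
            oa.fit_stage_gan(X, oa.GanConfig(**FAST_GAN))

    def test_non_finite_rejected(self):
        X, _ = _table([4], n_genes=3)
        X.iloc[0, 0] = np.inf
        with pytest.raises(ValueError, match="finite"):
            oa.fit_stage_gan(X, oa.GanConfig(**FAST_GAN))

    def test_sample_shapes_and_count_guard(self):
        X, _ = _table([10], n_genes=6)
        gen = oa.fit_stage_gan(X, oa.GanConfig(**FAST_GAN, seed=1))
        assert oa.sample_generator(gen, 7, seed=0).shape == (7, 6)
        with pytest.raises(ValueError):
            oa.sample_generator(gen, 0)

    def test_constant_training_data_degenerate_latent(self):
        ids = pd.Index([f"s{i}" for i in range(5)])
        X = pd.DataFrame(np.full((5, 3), 2.5), index=ids, columns=list("abc"))
        gen = oa.fit_stage_gan(X, oa.GanConfig(**FAST_GAN, seed=0))
        assert np.all(gen.latent.sd == 0.0)
        out = oa.sample_generator(gen, 4, seed=9)
        assert np.all(out == out[0])  # identical latent -> identical outputs

    def test_same_seed_bit_identical(self, toy_stage_data):
        cfg = oa.GanConfig(epochs=5, seed=11)
        a = oa.fit_stage_gan(toy_stage_data, cfg)
        b = oa.fit_stage_gan(toy_stage_data, cfg)
        assert np.array_equal(oa.sample_generator(a, 20, seed=3),
                              oa.sample_generator(b, 20, seed=3))

    def test_loss_trace_logged_per_epoch(self, toy_stage_data):
        gen = oa.fit_stage_gan(toy_stage_data, oa.GanConfig(epochs=4, seed=0))
        assert len(gen.history["d_loss"]) == 4
        assert len(gen.history["g_loss"]) == 4


class TestAugmentGan:
    def test_stage_ratio_exact(self):
        X, y = _table([5, 8, 3, 2])
        out = oa.augment_gan(X, y, fold=5, config=oa.GanConfig(**FAST_GAN))
        assert out.stage_counts() == {1: 25, 2: 40, 3: 15, 4: 10}
        assert out.method == "GAN" and out.fold == 5

    def test_fold_one_matches_training_total(self):
        X, y = _table([4, 6, 5, 3])
        out = oa.augment_gan(X, y, fold=1, config=oa.GanConfig(**FAST_GAN))
        assert len(out.expression) == len(X)

    def test_fold_100_multiplication(self):
        X, y = _table([2, 2], n_genes=2)
        out = oa.augment_gan(X, y, fold=100, config=oa.GanConfig(**FAST_GAN))
        assert len(out.expression) == 400

    def test_bad_fold_rejected(self):
        X, y = _table([3, 3])
        with pytest.raises(ValueError, match="fold"):
            oa.augment_gan(X, y, fold=0, config=oa.GanConfig(**FAST_GAN))


class TestMs:
    def test_constant_gene_reproduced_exactly(self):
        X, y = _table([6, 6], n_genes=3)
        X["g1"] = 4.25
        out = oa.augment_ms(X, y, seed=0)
        assert np.all(out.expression["g1"] == 4.25)

    def test_counts_mirror_training(self):
        X, y = _table([7, 3, 5, 4])
        out = oa.augment_ms(X, y, seed=1)
        assert out.stage_counts() == {1: 7, 2: 3, 3: 5, 4: 4}

    def test_half_sd_law_of_large_numbers(self):
        X, y = _table([10_000], n_genes=3, seed=2)
        out = oa.augment_ms(X, y, seed=3)
        target = X.std(ddof=1).to_numpy() / 2.0
        got = out.expression.std(ddof=1).to_numpy()
        assert np.all(np.abs(got - target) / target < 0.05)


class TestSmote:
    def test_oversamples_to_majority(self):
        X, y = _table([11, 38, 15, 6], n_genes=3, seed=4)
        out = oa.augment_smote(X, y, seed=0)
        assert out.stage_counts() == {1: 38, 2: 38, 3: 38, 4: 38}

    def test_balanced_input_unchanged(self):
        X, y = _table([6, 6, 6, 6], seed=5)
        out = oa.augment_smote(X, y, seed=0)
        assert len(out.expression) == len(X)
        np.testing.assert_array_equal(out.expression.to_numpy(), X.to_numpy())

    def test_single_sample_stage_rejected(self):
        X, y = _table([5, 1], n_genes=3)
        with pytest.raises(ValueError, match="single sample"):
            oa.augment_smote(X, y, seed=0)

    def test_synthetics_on_neighbour_segments(self):
        """Exhaustive: every synthetic point sits on a segment from a
        stage-mate to one of its k nearest stage-mates."""
        X, y = _table([9, 6], n_genes=3, seed=6)
        k = 3
        out = oa.augment_smote(X, y, k_neighbors=k, seed=1)
        synth = out.expression.iloc[len(X):].to_numpy()
        synth_y = out.stages.iloc[len(X):].to_numpy()
        assert len(synth) == 3  # 9 - 6
        for pt, s in zip(synth, synth_y):
            assert _on_some_segment(pt, X[y == s].to_numpy(), k)


def _on_some_segment(pt, stage_X, k, tol=1e-9):
    from scipy.spatial.distance import cdist
    D = cdist(stage_X, stage_X)
    np.fill_diagonal(D, np.inf)
    for i in range(len(stage_X)):
        for j in np.argsort(D[i])[:k]:
            a, b = stage_X[i], stage_X[j]
            ab = b - a
            denom = ab @ ab
            if denom == 0:
                continue
            t = (pt - a) @ ab / denom
            if -tol <= t <= 1 + tol and np.linalg.norm(a + t * ab - pt) < tol:
                return True
    return False


class TestDa:
    @pytest.mark.parametrize("n,m,expected", [
        (659, 19_738, 2_601_732),
        (1, 4, 1),
        (10, 10, 30),
    ])
    def test_count_rule(self, n, m, expected):
        assert oa.da_sample_count(n, m) == expected

    def test_corruption_mask_definition(self):
        X = np.arange(1.0, 25.0).reshape(2, 12)  # 2 samples, 12 genes, 2 windows
        corrupted, src = corrupt_windows(X)
        assert corrupted.shape == (4, 12)
        assert list(src) == [0, 0, 1, 1]
        # copy j differs from its source exactly in genes [5j, 5j+5)
        for row, (s, j) in zip(corrupted, [(0, 0), (0, 1), (1, 0), (1, 1)]):
            diff = np.flatnonzero(row != X[s])
            np.testing.assert_array_equal(diff, np.arange(5 * j, 5 * j + 5))
            assert np.all(row[diff] == 0.0)

    def test_output_count_and_labels(self):
        X, y = _table([4, 2], n_genes=12, seed=7)
        out = oa.augment_da(X, y, seed=0, epochs=5)
        assert len(out.expression) == oa.da_sample_count(6, 12)  # 18
        # labels inherited: originals plus 2 copies each
        assert out.stage_counts() == {1: 12, 2: 6}

    def test_reconstruction_loss_decreases(self):
        X, y = _table([30], n_genes=20, seed=8)
        for seed in range(3):
            out = oa.augment_da(X, y, seed=seed, epochs=40)
            loss = out.history["loss"]
            assert loss[-1] < loss[0]
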