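import numpy as np
import pandas as pd
import pytest

import omixaug as oa
from omixaug.evaluation import ExperimentConfig, VARIANTS


def _fast_config(**kw):
    defaults = dict(
        variants=("FS",), classifiers=("RF",), repeats=1, base_seed=0,
        gan=oa.GanConfig(hidden_units=8, epochs=2),
        cnn=oa.CnnConfig(epochs=2), dnn=oa.DnnConfig(epochs=20),
        da_epochs=5,
    )
    defaults.update(kw)
    return ExperimentConfig(**defaults)


class TestCompareTtest:
    def test_identical_vectors_p_one(self):
        assert oa.compare_ttest([0.5, 0.5, 0.5], [0.5, 0.5, 0.5]) == 1.0

    def test_separated_vectors_tiny_p(self):
        a = np.array([0.9, 0.9, 0.9, 0.9]) + 1e-4 * np.arange(4)
        b = np.array([0.1, 0.1, 0.1, 0.1]) + 1e-4 * np.arange(4)
        assert oa.compare_ttest(a, b) < 1e-6

    def test_matches_welch_closed_form(self):
        # independent oracle: Welch's t and df computed by hand
        from scipy.stats import t as tdist
        a = np.array([0.61, 0.58, 0.72, 0.66, 0.63])
        b = np.array([0.52, 0.49, 0.55, 0.47])
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        t_stat = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
        expected = 2 * tdist.sf(abs(t_stat), df)
        assert oa.compare_ttest(a, b) == pytest.approx(expected, abs=1e-10)

    def test_needs_two_values(self):
        with pytest.raises(ValueError):
            oa.compare_ttest([0.5], [0.4, 0.6])


def test_friedman_over_matched_repeats():
    rng = np.random.default_rng(0)
    base = rng.uniform(0.4, 0.6, size=10)
    M = np.vstack([base, base + 0.2, base + 0.21])  # two clearly better variants
    assert oa.compare_friedman(M) < 0.01


class TestPcaEmbed:
    def test_collinear_data_first_component_dominates(self):
        t = np.linspace(0, 1, 30)[:, None]
        X = t @ np.array([[1.0, 2.0, -1.0]])
        emb = oa.pca_embed(X[:15], X[15:])
        assert emb.explained_variance_ratio[0] >= 0.999

    def test_duplicated_dataset_clouds_coincide(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(25, 6))
        emb = oa.pca_embed(X, X)
        np.testing.assert_allclose(emb.original_coords, emb.generated_coords)
        np.testing.assert_allclose(emb.gene_coords_original,
                                   emb.gene_coords_generated)

    def test_generated_data_sharpens_stage_clusters(self, toy_stage_data):
        """Stage-1 vs stage-4 samples separate linearly after generation, and
        at least as crisply as the raw noisy data (the augmented-data PCA
        diagnostic)."""
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(2)
        n, m = 60, 10
        stages = {}
        gens = {}
        for s in (1, 4):
            X = pd.DataFrame(rng.normal(s * 1.0, 1.0, size=(n, m)),
                             columns=[f"g{j}" for j in range(m)])
            stages[s] = X
            g = oa.fit_stage_gan(X, oa.GanConfig(epochs=150, seed=s), stage=s)
            gens[s] = oa.sample_generator(g, n, seed=s + 50)
        Xg = np.vstack([gens[1], gens[4]])
        y = np.repeat([1, 4], n)
        acc = LogisticRegression(max_iter=500).fit(Xg, y).score(Xg, y)
        assert acc >= 0.9


class TestRunExperiment:
    def test_deterministic_rerun(self, tiny_cohort):
        cfg = _fast_config()
        genes = list(tiny_cohort.expression.columns[:5])
        a = oa.run_experiment(tiny_cohort, cfg, selected_genes=genes)
        b = oa.run_experiment(tiny_cohort, cfg, selected_genes=genes)
        pd.testing.assert_frame_equal(a.rows, b.rows)

    def test_row_grid_complete(self, tiny_cohort):
        cfg = _fast_config(variants=("Ori", "FS", "MS", "SMOTE", "GAN1"),
                           classifiers=("RF", "DNN"), repeats=2)
        genes = list(tiny_cohort.expression.columns[:5])
        table = oa.run_experiment(tiny_cohort, cfg, selected_genes=genes)
        assert len(table.rows) == 5 * 2 * 2
        counts = table.rows.groupby(["variant", "classifier"]).size()
        assert (counts == 2).all()

    def test_summary_recomputable_from_rows(self, tiny_cohort):
        cfg = _fast_config(repeats=3)
        genes = list(tiny_cohort.expression.columns[:5])
        table = oa.run_experiment(tiny_cohort, cfg, selected_genes=genes)
        s = table.summary()
        by_hand = table.rows.groupby(["variant", "classifier"])["accuracy"].mean()
        got = s.set_index(["variant", "classifier"])["accuracy_mean"]
        pd.testing.assert_series_equal(got, by_hand, check_names=False)

    def test_variant_names_validated(self):
        with pytest.raises(ValueError, match="unknown variants"):
            _fast_config(variants=("Orii",))

    def test_all_nine_variants_accepted(self):
        cfg = _fast_config(variants=VARIANTS)
        assert set(cfg.variants) == set(VARIANTS)


class TestConsistencyContracts:
    def test_fold_sweep_rows_and_gan1_consistency(self, tiny_cohort):
        cfg = _fast_config(classifiers=("1DCNN",), repeats=2,
                           cnn=oa.CnnConfig(epochs=2))
        genes = list(tiny_cohort.expression.columns[:13])
        sweep = oa.fold_sweep(tiny_cohort, folds=(1, 5), config=cfg,
                              selected_genes=genes)
        assert len(sweep.rows) == 2 * 2
        run = oa.run_experiment(
            tiny_cohort, _fast_config(variants=("GAN1",), classifiers=("1DCNN",),
                                      repeats=2, cnn=oa.CnnConfig(epochs=2)),
            selected_genes=genes)
        np.testing.assert_allclose(sweep.metric_vector("GAN1", "1DCNN"),
                                   run.metric_vector("GAN1", "1DCNN"))

    def test_subsample_full_fraction_matches_fs_experiment(self, tiny_cohort):
        genes = list(tiny_cohort.expression.columns[:13])
        cfg = _fast_config(classifiers=("1DCNN",), repeats=2,
                           cnn=oa.CnnConfig(epochs=2))
        sub = oa.subsample_experiment(tiny_cohort, fractions=(1.0,), fold=1,
                                      config=cfg, selected_genes=genes)
        run = oa.run_experiment(
            tiny_cohort, _fast_config(variants=("FS",), classifiers=("1DCNN",),
                                      repeats=2, cnn=oa.CnnConfig(epochs=2)),
            selected_genes=genes)
        np.testing.assert_allclose(sub.metric_vector("100O", "1DCNN"),
                                   run.metric_vector("FS", "1DCNN"))

    def test_infeasible_fraction_rejected(self, tiny_cohort):
        with pytest.raises(ValueError, match="fraction"):
            oa.subsample_experiment(tiny_cohort, fractions=(0.1,),
                                    config=_fast_config(),
                                    selected_genes=list(
                                        tiny_cohort.expression.columns[:5]))
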