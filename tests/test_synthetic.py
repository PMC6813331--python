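import numpy as np
import pandas as pd
import pytest

from micronetfun import (
    SyntheticConfig,
    generate_counts,
    generate_dataset,
    generate_functions,
    generate_true_graph,
)
from micronetfun.synthetic import SyntheticTruth, sample_latent


class TestTrueGraph:
    def test_zero_density_gives_diagonal_precision(self):
        cfg = SyntheticConfig(n_bacteria=10, n_fungi=5, graph_density=0.0, seed=0)
        truth = generate_true_graph(cfg)
        prec = truth.precision.to_numpy()
        assert truth.true_edges == set()
        assert np.allclose(prec, np.diag(np.diag(prec)))

    def test_single_edge_markov_chain_independence(self):
        # precision zero between non-adjacent taxa <=> zero partial corr
        cfg = SyntheticConfig(n_bacteria=2, n_fungi=1, graph_density=0.0, seed=0)
        truth = generate_true_graph(cfg)
        ids = truth.precision.columns
        omega = truth.precision.to_numpy().copy()
        omega[0, 1] = omega[1, 0] = -0.4
        truth = SyntheticTruth(
            true_edges={(ids[0], ids[1])},
            precision=pd.DataFrame(omega, index=ids, columns=ids),
        )
        cov = np.linalg.inv(omega)
        # taxa 0 and 2 are conditionally independent given taxon 1
        assert omega[0, 2] == 0.0
        assert cov[0, 2] == pytest.approx(cov[0, 1] * cov[1, 2] / cov[1, 1])

    def test_edge_count_matches_density(self):
        cfg = SyntheticConfig(n_bacteria=30, n_fungi=20, graph_density=0.02,
                              seed=1)
        truth = generate_true_graph(cfg)
        expected = 0.02 * 50 * 49 / 2
        # direct count of off-diagonal nonzeros agrees with the edge set
        prec = truth.precision.to_numpy()
        nnz = int((np.abs(np.triu(prec, 1)) > 0).sum())
        assert nnz == len(truth.true_edges)
        assert abs(nnz - expected) <= 0.2 * expected

    def test_precision_positive_definite(self):
        cfg = SyntheticConfig(graph_density=0.05, seed=2)
        truth = generate_true_graph(cfg)
        assert np.linalg.eigvalsh(truth.precision.to_numpy())[0] > 0

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"graph_density": 1.5},
            {"retention_fractions": (0.5, 0.6, 0.4, 0.3, 0.2, 0.1)},
            {"n_bacteria": 0},
            {"noise_sd": -1.0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SyntheticConfig(**kwargs)


class TestCounts:
    def test_rows_sum_to_depth(self, small_dataset):
        otu, _, _ = small_dataset
        assert (otu.abundance.sum(axis=1) == 2000).all()

    def test_masked_taxa_have_zero_counts(self, small_dataset, small_config):
        otu, _, truth = small_dataset
        masked = ~truth.presence_mask
        assert (otu.abundance.to_numpy()[masked.to_numpy()] == 0).all()

    def test_level_masks_nested(self, small_dataset):
        _, _, truth = small_dataset
        masks = truth.level_masks.to_numpy()
        for lv in range(1, masks.shape[0]):
            # taxa present at a sparser level are present at all richer ones
            assert not (masks[lv] & ~masks[lv - 1]).any()

    def test_sample_presence_subset_of_level_mask(self, small_dataset, small_config):
        _, _, truth = small_dataset
        for sid, row in truth.presence_mask.iterrows():
            lv = truth._sample_meta.loc[sid, "level"]
            assert not (row.to_numpy() & ~truth.level_masks.loc[lv].to_numpy()).any()

    def test_realized_richness_monotone_in_level(self, small_dataset):
        otu, _, _ = small_dataset
        rich = (otu.abundance > 0).sum(axis=1)
        means = rich.groupby(otu.sample_meta["level"]).mean()
        assert (means.diff().dropna() <= 0).all()

    def test_seed_reproducibility_bitwise(self, small_config):
        a = generate_dataset(small_config)
        b = generate_dataset(small_config)
        pd.testing.assert_frame_equal(a[0].abundance, b[0].abundance)
        pd.testing.assert_frame_equal(a[1].values, b[1].values)
        assert a[2].true_edges == b[2].true_edges

    def test_zero_depth_rejected(self, small_config):
        truth = generate_true_graph(small_config)
        import dataclasses

        bad = dataclasses.replace(small_config)
        bad.sequencing_depth = 0
        with pytest.raises(ValueError):
            generate_counts(truth, bad)

    def test_positive_coupling_shows_in_clr_correlation(self):
        """A strong planted positive partial correlation must surface as a
        positive CLR-abundance correlation in nearly all replicate
        datasets."""
        p = 10
        ids = pd.Index([f"b_{i+1:04d}" for i in range(6)]
                       + [f"f_{i+1:04d}" for i in range(4)])
        omega = np.eye(p)
        omega[0, 1] = omega[1, 0] = -0.8  # partial correlation +0.8
        hits = 0
        n_rep = 60
        for rep in range(n_rep):
            cfg = SyntheticConfig(
                n_bacteria=6, n_fungi=4, n_levels=2,
                retention_fractions=(1.0, 0.99), reps_per_level=20,
                sterile_reps=20, sequencing_depth=5000, dropout=0.0,
                supporter_pool_level=1, seed=10_000 + rep,
            )
            truth = SyntheticTruth(
                true_edges={(ids[0], ids[1])},
                precision=pd.DataFrame(omega, index=ids, columns=ids),
            )
            otu = generate_counts(truth, cfg)
            counts = otu.abundance.to_numpy() + 0.5  # pseudocount
            logp = np.log(counts / counts.sum(axis=1, keepdims=True))
            clr = logp - logp.mean(axis=1, keepdims=True)
            r = np.corrcoef(clr[:, 0], clr[:, 1])[0, 1]
            hits += r > 0
        assert hits >= 0.95 * n_rep


class TestFunctions:
    def test_three_loss_functions_flagged(self, small_dataset):
        _, functions, _ = small_dataset
        loss = functions.direction[functions.direction == "loss"].index
        assert set(loss) == {"N_leaching", "P_leaching", "N2O_emission"}

    def test_zero_effect_gives_pure_noise(self, small_config):
        import dataclasses

        cfg = dataclasses.replace(small_config)
        cfg.effect_size = 0.0
        otu, functions, truth = generate_dataset(cfg)
        assert all(len(s) == 0 for s in truth.supporter_sets.values())

    def test_noiseless_single_supporter_equals_zscored_abundance(self):
        cfg = SyntheticConfig(
            n_bacteria=20, n_fungi=10, supporters_per_function=1,
            noise_sd=0.0, effect_size=1.0, supporter_positive_fraction=1.0,
            seed=5,
        )
        otu, functions, truth = generate_dataset(cfg)
        nm = "forb_N_uptake"
        (supporter,) = truth.supporter_sets[nm]
        w = truth.effect_weights[nm][supporter]
        prop = otu.abundance.div(otu.abundance.sum(axis=1), axis=0)[supporter]
        z = (prop - prop.mean()) / prop.std(ddof=1)
        np.testing.assert_allclose(functions.values[nm].to_numpy(),
                                   w * z.to_numpy(), atol=1e-12)

    def test_oracle_regression_on_true_supporters(self, small_dataset):
        """Regressing a function on its planted supporters recovers most of
        the variance at the default signal/noise settings."""
        import statsmodels.api as sm

        otu, functions, truth = small_dataset
        prop = otu.abundance.div(otu.abundance.sum(axis=1), axis=0)
        r2 = []
        for nm, weights in truth.effect_weights.items():
            X = prop[list(weights)].to_numpy()
            y = functions.adjusted()[nm].to_numpy()
            r2.append(sm.OLS(y, sm.add_constant(X)).fit().rsquared)
        assert np.mean(r2) >= 0.6

    def test_latent_samples_match_planted_correlation(self):
        cfg = SyntheticConfig(n_bacteria=3, n_fungi=2, graph_density=0.0, seed=0)
        truth = generate_true_graph(cfg)
        X = sample_latent(truth, 4000, seed=9)
        # independent taxa: sample correlations near zero
        off = np.corrcoef(X.to_numpy(), rowvar=False)[np.triu_indices(5, 1)]
        assert np.abs(off).max() < 0.08
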