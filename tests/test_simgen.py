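import numpy as np
import pytest

import dmbench as d
from dmbench.simgen import SimConfig, apply_effects


class TestSpikeTruth:
    def test_no_association_forces_zero_effects(self):
        t = d.draw_spike_truth(5, p_assoc=0.0, seed=1)
        assert np.all(t.beta == 0) and np.all(t.eta == 0)

    def test_bernoulli_rate(self):
        J = 100_000
        t = d.draw_spike_truth(J, p_assoc=0.5, seed=2)
        assert abs(t.eta.mean() - 0.5) < 3 * np.sqrt(0.25 / J)

    def test_scaled_t_effect_sd(self):
        # sd of a scaled t(7) is scale * sqrt(7/5)
        t = d.draw_spike_truth(200_000, p_assoc=1.0, effect_df=7, effect_scale=2.5, seed=3)
        expected = 2.5 * np.sqrt(7 / 5)
        assert abs(np.std(t.gamma) / expected - 1) < 0.01

    def test_beta_consistency(self):
        t = d.draw_spike_truth(1000, p_assoc=0.4, seed=4)
        assert np.count_nonzero(t.beta) == np.sum(t.eta == 1)
        np.testing.assert_array_equal(t.beta[t.eta == 1], t.gamma[t.eta == 1])

    @pytest.mark.parametrize("kwargs", [dict(J=0), dict(J=5, effect_df=-1),
                                        dict(J=5, effect_scale=0), dict(J=5, p_assoc=1.5)])
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(ValueError):
            d.draw_spike_truth(**{"p_assoc": 0.5, "effect_df": 7.0,
                                  "effect_scale": 2.5, **kwargs})


class TestBaselineProportions:
    def test_rows_on_simplex(self):
        th = d.draw_baseline_proportions(np.array([0.5, 1.0, 3.0]), 200, seed=1)
        np.testing.assert_allclose(th.sum(axis=1), 1.0, atol=1e-12)

    def test_dirichlet_mean(self):
        th = d.draw_baseline_proportions(np.array([2.0, 3.0, 5.0]), 100_000, seed=2)
        np.testing.assert_allclose(th.mean(axis=0), [0.2, 0.3, 0.5], atol=0.005)

    def test_rejects_nonpositive_pi(self):
        with pytest.raises(ValueError):
            d.draw_baseline_proportions(np.array([1.0, 0.0]), 10)


class TestApplyEffects:
    def test_null_effects_reproduce_theta_exactly(self):
        th = d.draw_baseline_proportions(np.array([1.0, 2.0, 3.0]), 50, seed=3)
        mu = apply_effects(th, np.zeros(3), np.linspace(-2, 2, 50))
        np.testing.assert_array_equal(mu, th)

    def test_zero_covariate_rows_unchanged(self):
        th = d.draw_baseline_proportions(np.array([1.0, 2.0]), 4, seed=4)
        x = np.array([0.0, 1.0, 0.0, -1.0])
        mu = apply_effects(th, np.array([1.5, 0.0]), x)
        np.testing.assert_array_equal(mu[x == 0], th[x == 0])
        assert not np.array_equal(mu[x != 0], th[x != 0])

    def test_hand_computed_shift(self):
        # logit(0.2) + 1 = -0.3863 -> 0.4046; renormalize (0.4046, 0.8)
        mu = apply_effects(np.array([[0.2, 0.8]]), np.array([1.0, 0.0]), np.array([1.0]))
        np.testing.assert_allclose(mu[0], [0.33588, 0.66412], atol=1e-5)

    def test_boundary_theta_warns(self):
        th = np.array([[0.0, 1.0]])
        with pytest.warns(RuntimeWarning):
            mu = apply_effects(th, np.array([1.0, 1.0]), np.array([2.0]))
        assert np.isfinite(mu).all() and abs(mu.sum() - 1) < 1e-9


class TestLibrarySizes:
    def test_degenerate_lognormal(self):
        N = d.draw_library_sizes(10, 1234.4, 0.0, seed=1)
        assert np.all(N == 1234)

    def test_median_matches_target_depth(self):
        N = d.draw_library_sizes(100_000, 50_000, 0.77, seed=2)
        assert abs(np.median(N) / 50_000 - 1) < 0.02

    def test_log_sd_recovers_sigma(self):
        N = d.draw_library_sizes(100_000, 50_000, 0.77, seed=3)
        assert abs(np.std(np.log(N)) / 0.77 - 1) < 0.02


class TestCounts:
    def test_row_sums_equal_library_sizes(self, rng):
        mu = rng.dirichlet(np.ones(5), size=20)
        N = rng.integers(100, 1000, 20)
        y = d.draw_counts(mu, N, seed=1)
        np.testing.assert_array_equal(y.sum(axis=1), N)

    def test_single_otu_gets_everything(self):
        y = d.draw_counts(np.ones((4, 1)), np.array([5, 6, 7, 8]), seed=2)
        np.testing.assert_array_equal(y[:, 0], [5, 6, 7, 8])

    def test_multinomial_mean(self, rng):
        p = np.array([0.1, 0.3, 0.6])
        y = d.draw_counts(np.tile(p, (4000, 1)), np.full(4000, 10_000), seed=3)
        mc_sd = np.sqrt(10_000 * p * (1 - p) / 4000)
        assert np.all(np.abs(y.mean(axis=0) - 10_000 * p) < 3 * mc_sd)

    def test_rejects_off_simplex_rows(self):
        with pytest.raises(ValueError):
            d.draw_counts(np.array([[0.5, 0.2]]), np.array([10]))


class TestSimulateDataset:
    def test_shapes_and_conservation(self, small_dataset):
        ds = small_dataset
        assert ds.y.shape == (300, 80) and ds.x.size == 300
        np.testing.assert_array_equal(ds.y.sum(axis=1), ds.N)

    def test_seed_determinism(self):
        pi = d.generate_synthetic_pi(40, seed=9)
        cfg = d.SimConfig(pi=pi.pi, n_subjects=50, mean_depth=2000, seed=11)
        a, b = d.simulate_dataset(cfg), d.simulate_dataset(cfg)
        np.testing.assert_array_equal(a.y, b.y)
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.N, b.N)
        np.testing.assert_array_equal(a.truth.beta, b.truth.beta)

    def test_lower_depth_means_more_zeros(self):
        pi = d.generate_synthetic_pi(60, seed=13)
        base = dict(pi=pi.pi, n_subjects=150, seed=17)
        shallow = d.simulate_dataset(SimConfig(mean_depth=500, **base))
        deep = d.simulate_dataset(SimConfig(mean_depth=50_000, **base))
        assert (shallow.y == 0).mean() > (deep.y == 0).mean()


class TestDiagnostics:
    def test_hand_computed_column_stats(self):
        y = np.array([[2, 0], [2, 0], [2, 4]])
        g = d.dataset_diagnostics(y)
        np.testing.assert_allclose(g["otu_mean"], [2, 4 / 3])
        np.testing.assert_allclose(g["otu_zero_fraction"], [0, 2 / 3])
        assert g["otu_variance"][0] == 0

    def test_simulated_data_overdispersed(self, small_dataset):
        g = d.dataset_diagnostics(small_dataset.y)
        # most reasonably abundant OTUs exceed Poisson variance
        abundant = g["otu_mean"] > 5
        frac = (g["otu_variance"][abundant] > g["otu_mean"][abundant]).mean()
        assert frac > 0.9

    def test_rejects_empty_and_negative(self):
        with pytest.raises(ValueError):
            d.dataset_diagnostics(np.empty((0, 0)))
        with pytest.raises(ValueError):
            d.dataset_diagnostics(np.array([[-1, 2]]))
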