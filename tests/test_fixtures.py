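import numpy as np
import pytest

import dmbench as d
from dmbench.fixtures import dirichlet_multinomial_loglik, fit_dirichlet_multinomial


def _dm_counts(pi, n, depth, seed):
    rng = np.random.default_rng(seed)
    th = rng.dirichlet(pi, size=n)
    N = rng.integers(depth // 2, depth * 2, n)
    return np.vstack([rng.multinomial(N[i], th[i]) for i in range(n)])


class TestDirichletMultinomialFit:
    def test_parameter_recovery(self):
        y = _dm_counts(np.array([2.0, 3.0, 5.0]), 2000, 5000, seed=1)
        tpl = fit_dirichlet_multinomial(y)
        np.testing.assert_allclose(tpl.direction, [0.2, 0.3, 0.5], rtol=0.05)
        assert abs(tpl.concentration / 10 - 1) < 0.2

    def test_loglik_nondecreasing(self):
        y = _dm_counts(np.array([0.5, 1.0, 4.0, 0.2]), 300, 2000, seed=2)
        _, trace = fit_dirichlet_multinomial(y, return_loglik=True)
        assert np.all(np.diff(trace) >= -1e-6 * np.abs(trace[:-1]))

    def test_permutation_equivariance(self):
        y = _dm_counts(np.array([1.0, 2.0, 7.0]), 500, 3000, seed=3)
        perm = [2, 0, 1]
        a = fit_dirichlet_multinomial(y)
        b = fit_dirichlet_multinomial(y[:, perm])
        np.testing.assert_allclose(b.pi, a.pi[perm], rtol=1e-6)

    def test_all_zero_column_dropped_with_warning(self):
        y = _dm_counts(np.array([1.0, 2.0, 7.0]), 100, 1000, seed=4)
        y = np.hstack([y, np.zeros((100, 1), dtype=int)])
        with pytest.warns(RuntimeWarning):
            tpl = fit_dirichlet_multinomial(y)
        assert tpl.pi.size == 3

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_dirichlet_multinomial(np.array([[1, 2, 3]]))

    def test_loglik_matches_direct_formula(self):
        # independent check of the objective on a tiny instance
        from scipy.special import gammaln

        y = np.array([[2, 1], [0, 3]], dtype=float)
        pi = np.array([1.5, 0.5])
        manual = 0.0
        for row in y:
            Ntot, a0 = row.sum(), pi.sum()
            manual += gammaln(a0) - gammaln(Ntot + a0)
            manual += np.sum(gammaln(row + pi) - gammaln(pi))
        assert abs(dirichlet_multinomial_loglik(y, pi) - manual) < 1e-10


class TestLognormalFit:
    def test_hand_mle(self):
        m = d.fit_lognormal(np.exp([10.0, 12.0]))
        assert m.mu_L == pytest.approx(11.0) and m.sigma_L == pytest.approx(1.0)

    def test_constant_depths(self):
        m = d.fit_lognormal(np.full(10, 777.0))
        assert m.sigma_L == pytest.approx(0.0, abs=1e-12)

    def test_recovers_generative_sigma(self, rng):
        N = np.exp(rng.normal(np.log(50_000), 0.77, 100_000))
        m = d.fit_lognormal(N)
        assert abs(m.sigma_L / 0.77 - 1) < 0.01
        assert m.median_depth == pytest.approx(50_000, rel=0.02)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            d.fit_lognormal(np.array([100.0, 0.0]))


class TestSyntheticPi:
    def test_heavy_tail_dominance(self):
        tpl = d.generate_synthetic_pi(300, tail_shape=2.0, seed=1)
        assert np.sort(tpl.direction)[-10:].sum() > 0.5

    def test_concentration_scales_without_changing_direction(self):
        a = d.generate_synthetic_pi(100, concentration=10, seed=2)
        b = d.generate_synthetic_pi(100, concentration=500, seed=2)
        np.testing.assert_allclose(a.direction, b.direction)
        assert b.concentration == pytest.approx(500)

    def test_seed_determinism(self):
        a = d.generate_synthetic_pi(50, seed=3)
        b = d.generate_synthetic_pi(50, seed=3)
        np.testing.assert_array_equal(a.pi, b.pi)

    def test_roundtrip_recovery_through_simulator(self):
        # simulate under the synthetic composition with no spike-ins, refit,
        # and recover the direction
        tpl = d.generate_synthetic_pi(60, seed=4)
        cfg = d.SimConfig(pi=tpl.pi, n_subjects=1000, mean_depth=50_000,
                          p_assoc=0.0, seed=5)
        ds = d.simulate_dataset(cfg)
        refit = fit_dirichlet_multinomial(ds.y)
        a, b = refit.direction, tpl.direction
        cosine = a @ b / np.sqrt((a @ a) * (b @ b))
        assert cosine > 0.99
        assert np.corrcoef(a, b)[0, 1] > 0.99


class TestDietaryVariable:
    def test_exact_standardization(self):
        x = d.generate_dietary_variable(500, skew_target=2.0, seed=1)
        assert abs(x.mean()) < 1e-12 and abs(x.std(ddof=0) - 1) < 1e-12

    def test_symmetric_member(self):
        x = d.generate_dietary_variable(10_000, skew_target=0.0, seed=2)
        assert abs(d.sample_skewness(x)) < 0.1

    def test_skewness_monotone_in_target(self):
        sk = [d.sample_skewness(d.generate_dietary_variable(10_000, t, seed=3))
              for t in (0, 1, 2, 4)]
        assert np.all(np.diff(sk) > 0)

    def test_zero_inflation_creates_point_mass(self):
        x = d.generate_dietary_variable(2000, 1.0, seed=4, zero_inflation=0.3)
        # the inflated mass sits at one standardized value
        vals, counts = np.unique(x, return_counts=True)
        assert counts.max() > 0.2 * x.size

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            d.generate_dietary_variable(2, 0.0)


class TestTemplateSampling:
    def test_draws_come_from_template(self, tmp_path, rng):
        import pandas as pd

        df = pd.DataFrame({"fiber": rng.normal(size=40), "fat": rng.normal(size=40)})
        p = tmp_path / "ffq.tsv"
        df.to_csv(p, sep="\t", index=False)
        x = d.sample_covariate_from_template(p, "fiber", 500, seed=1)
        assert x.size == 500  # n may exceed the template length
        # restandardized draws are affine images of template members
        raw = np.random.default_rng(1).choice(df["fiber"].to_numpy(), 500, replace=True)
        assert abs(x.mean()) < 1e-12 and abs(x.std(ddof=0) - 1) < 1e-12

    def test_ecdf_converges_to_template(self, rng):
        import pandas as pd
        from scipy.stats import ks_2samp

        col = rng.standard_normal(5000)
        col = (col - col.mean()) / col.std(ddof=0)
        df = pd.DataFrame({"v": col})
        x = d.sample_covariate_from_template(df, "v", 100_000, seed=2)
        assert ks_2samp(x, col).statistic < 0.02

    def test_missing_column(self):
        import pandas as pd

        with pytest.raises(KeyError):
            d.sample_covariate_from_template(pd.DataFrame({"a": [1.0, 2.0]}), "b", 5)
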