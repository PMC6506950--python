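import numpy as np
import pytest

import dmbench as d
from dmbench.benchmark import BenchmarkConfig, run_benchmark

# the desk-scale study conditions shared by the acceptance
# tests: 50 simulations, 500 subjects, 300 OTUs, mean depth 20,000,
# lognormal depth sd 0.77, Bernoulli(0.5) spike-ins with t7(0, 2.5) effects,
# synthetic heavy-tailed composition, FFQ-like skewed covariates
BENCH_CONFIG = BenchmarkConfig(n_simulations=50, n_subjects=500, n_otus=300,
                               mean_depth=20_000.0, sigma_L=0.77, seed=1)


@pytest.fixture(scope="session")
def benchmark_summary():
    """One full desk-scale benchmark, shared across acceptance tests."""
    return run_benchmark(BENCH_CONFIG)


@pytest.fixture(scope="session")
def small_dataset():
    """A quick 300 x 80 simulated dataset for pipeline-level tests."""
    pi = d.generate_synthetic_pi(80, seed=5)
    x = d.generate_dietary_variable(300, skew_target=0.8, seed=6)
    cfg = d.SimConfig(pi=pi.pi, n_subjects=300, mean_depth=8000.0,
                      covariate_source=x, seed=7)
    return d.simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
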