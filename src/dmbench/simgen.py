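"""Generative model for 16S OTU count tables with spiked-in covariate effects.

The simulator plants known associations between a single standardized
continuous covariate (a dietary variable) and OTU relative abundances:

1. eta_j ~ Bernoulli(p_assoc) marks which OTUs are truly associated,
2. gamma_j ~ t(df) * scale is the raw effect on the logit scale,
3. beta_j = eta_j * gamma_j,
4. theta_i. ~ Dirichlet(pi) is the subject's baseline composition,
5. logit(mu_ij) = logit(theta_ij) + beta_j * x_i (rows renormalized),
6. N_i ~ round(Lognormal(log(mean_depth), sigma_L)),
7. y_i. ~ Multinomial(N_i, mu_i.).

Because the logit shift acts entrywise it leaves the simplex; each row of mu
is renormalized so the multinomial in step 7 is well defined.  With beta = 0
(or x_i = 0) the affected entries are left untouched, so the null model
reproduces theta exactly.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Union

import numpy as np
from scipy.special import expit, logit as _logit

__all__ = [
    "SpikeTruth",
    "SimConfig",
    "SimulatedDataset",
    "draw_spike_truth",
    "draw_baseline_proportions",
    "apply_effects",
    "draw_library_sizes",
    "draw_counts",
    "simulate_dataset",
    "dataset_diagnostics",
]

# clamp for theta before taking logits; Dirichlet draws at tiny pi entries
# underflow to exactly 0, where the logit is undefined
_THETA_EPS = 1e-12


@dataclass(frozen=True)
class SpikeTruth:
    """Per-OTU ground truth of the planted associations."""

    eta: np.ndarray  # binary indicator, length J
    gamma: np.ndarray  # raw effect, logit scale, length J
    beta: np.ndarray  # realized effect = eta * gamma, length J

    def __post_init__(self) -> None:
        eta = np.asarray(self.eta)
        if not np.isin(eta, (0, 1)).all():
            raise ValueError("eta must be binary")
        if len(self.eta) != len(self.gamma) or len(self.eta) != len(self.beta):
            raise ValueError("eta, gamma, beta must have equal length")
        if np.any(self.beta[eta == 0] != 0):
            raise ValueError("beta must be 0 where eta == 0")

    @property
    def n_otus(self) -> int:
        return len(self.eta)


@dataclass(frozen=True)
class SimConfig:
    """All generative-model parameters for one simulated dataset.

    Defaults mirror the reference study conditions: 1000 subjects, mean
    sequencing depth 50,000 reads, lognormal depth sd 0.77 on the log scale,
    half the OTUs associated, effects drawn from a t distribution with 7
    degrees of freedom and scale 2.5.
    """

    pi: np.ndarray  # Dirichlet parameter, length J, all > 0
    n_subjects: int = 1000
    mean_depth: float = 50_000.0
    sigma_L: float = 0.77
    p_assoc: float = 0.5
    effect_df: float = 7.0
    effect_scale: float = 2.5
    # either a vector of length n_subjects or a callable (n, rng) -> vector
    covariate_source: Union[np.ndarray, Callable, None] = None
    seed: int = 0

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        if pi.ndim != 1 or pi.size < 1 or np.any(pi <= 0) or not np.all(np.isfinite(pi)):
            raise ValueError("pi must be a 1-d vector of positive finite entries")
        object.__setattr__(self, "pi", pi)
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if self.sigma_L < 0:
            raise ValueError("sigma_L must be >= 0")
        if not 0.0 <= self.p_assoc <= 1.0:
            raise ValueError("p_assoc must lie in [0, 1]")
        if self.effect_df <= 0 or self.effect_scale <= 0:
            raise ValueError("effect_df and effect_scale must be > 0")

    @property
    def n_otus(self) -> int:
        return int(self.pi.size)

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class SimulatedDataset:
    """One simulated study: covariate, library sizes, counts and truth."""

    x: np.ndarray  # standardized covariate, length n
    N: np.ndarray  # integer library sizes, length n
    y: np.ndarray  # counts, n x J
    truth: SpikeTruth
    theta: Optional[np.ndarray] = None  # baseline proportions, n x J
    mu: Optional[np.ndarray] = None  # effect-modified proportions, n x J
    config: Optional[SimConfig] = field(default=None, compare=False)

    @property
    def n_subjects(self) -> int:
        return self.y.shape[0]

    @property
    def n_otus(self) -> int:
        return self.y.shape[1]

    @property
    def otu_ids(self) -> np.ndarray:
        return np.array([f"OTU{j + 1}" for j in range(self.n_otus)])


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def draw_spike_truth(
    J: int,
    p_assoc: float = 0.5,
    effect_df: float = 7.0,
    effect_scale: float = 2.5,
    seed=0,
) -> SpikeTruth:
    """Draw per-OTU association indicators and effect sizes.

    eta_j ~ Bernoulli(p_assoc); gamma_j ~ effect_scale * t(effect_df);
    beta_j = eta_j * gamma_j.
    """
    if J < 1:
        raise ValueError("J must be >= 1")
    if not 0.0 <= p_assoc <= 1.0:
        raise ValueError("p_assoc must lie in [0, 1]")
    if effect_df <= 0 or effect_scale <= 0:
        raise ValueError("effect_df and effect_scale must be > 0")
    rng = _rng(seed)
    eta = rng.binomial(1, p_assoc, size=J)
    gamma = effect_scale * rng.standard_t(effect_df, size=J)
    beta = eta * gamma
    return SpikeTruth(eta=eta, gamma=gamma, beta=beta)


def draw_baseline_proportions(pi: np.ndarray, n: int, seed=0) -> np.ndarray:
    """Draw n i.i.d. baseline compositions theta_i. ~ Dirichlet(pi)."""
    pi = np.asarray(pi, dtype=float)
    if np.any(pi <= 0):
        raise ValueError("all pi entries must be > 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)
    # gamma-normalization form; rng.dirichlet underflows identically but this
    # keeps one code path for very small shape parameters
    g = rng.standard_gamma(np.broadcast_to(pi, (n, pi.size)))
    total = g.sum(axis=1, keepdims=True)
    # guard against an all-underflow row (astronomically unlikely unless all
    # pi entries are tiny)
    bad = total[:, 0] == 0
    if bad.any():
        g[bad] = 1.0 / pi.size
        total = g.sum(axis=1, keepdims=True)
    return g / total


def apply_effects(theta: np.ndarray, beta: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Shift logit(theta_ij) by beta_j * x_i and renormalize rows.

    Entries with beta_j * x_i == 0 are copied through unchanged, so a null
    effect vector reproduces theta exactly.  theta entries at 0 or 1 are
    clamped into (0, 1) before the logit with a warning.
    """
    theta = np.asarray(theta, dtype=float)
    beta = np.asarray(beta, dtype=float)
    x = np.asarray(x, dtype=float)
    if theta.ndim != 2 or theta.shape[1] != beta.size or theta.shape[0] != x.size:
        raise ValueError("shape mismatch between theta, beta and x")
    if np.any(theta < 0) or np.any(theta > 1):
        raise ValueError("theta entries must lie in [0, 1]")

    shift = np.outer(x, beta)
    if not shift.any():
        return theta.copy()

    at_boundary = (theta <= 0) | (theta >= 1)
    if at_boundary.any():
        warnings.warn(
            f"{int(at_boundary.sum())} theta entries at the simplex boundary "
            f"clamped to [{_THETA_EPS}, 1-{_THETA_EPS}] before logit",
            RuntimeWarning,
            stacklevel=2,
        )
    th = np.clip(theta, _THETA_EPS, 1.0 - _THETA_EPS)
    mu = np.where(shift == 0.0, theta, expit(_logit(th) + shift))
    return mu / mu.sum(axis=1, keepdims=True)


def draw_library_sizes(n: int, mean_depth: float, sigma_L: float, seed=0) -> np.ndarray:
    """Draw integer library sizes N_i = round(exp(z_i)), z ~ N(log depth, sigma_L^2)."""
    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    if sigma_L < 0:
        raise ValueError("sigma_L must be >= 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)
    z = rng.normal(np.log(mean_depth), sigma_L, size=n)
    N = np.rint(np.exp(z)).astype(np.int64)
    return np.maximum(N, 1)


def draw_counts(mu: np.ndarray, N: np.ndarray, seed=0) -> np.ndarray:
    """Draw y_i. ~ Multinomial(N_i, mu_i.) for each sample row."""
    mu = np.asarray(mu, dtype=float)
    N = np.asarray(N)
    if mu.ndim != 2 or mu.shape[0] != N.size:
        raise ValueError("mu must be n x J with one row per library size")
    if np.any(N < 0):
        raise ValueError("library sizes must be >= 0")
    row_sums = mu.sum(axis=1)
    if np.any(np.abs(row_sums - 1.0) > 1e-6) or np.any(mu < 0):
        raise ValueError("each row of mu must be a probability vector")
    rng = _rng(seed)
    # exact renormalization; rng.multinomial tolerates only tiny deviations
    p = mu / row_sums[:, None]
    return rng.multinomial(N.astype(np.int64), p)


def simulate_dataset(config: SimConfig, keep_intermediates: bool = False) -> SimulatedDataset:
    """Run the full generative pipeline for one dataset.

    One root seed expands to independent per-stage streams (truth, covariate,
    baseline, library sizes, counts), so changing one stage's parameters does
    not perturb the draws of the others.
    """
    ss = np.random.SeedSequence(config.seed)
    s_truth, s_cov, s_theta, s_depth, s_counts = ss.spawn(5)

    truth = draw_spike_truth(
        config.n_otus, config.p_assoc, config.effect_df, config.effect_scale, seed=s_truth
    )

    src = config.covariate_source
    if src is None:
        x = _rng(s_cov).standard_normal(config.n_subjects)
        x = (x - x.mean()) / x.std(ddof=0)
    elif callable(src):
        x = np.asarray(src(config.n_subjects, _rng(s_cov)), dtype=float)
    else:
        x = np.asarray(src, dtype=float)
    if x.size != config.n_subjects:
        raise ValueError("covariate length does not match n_subjects")

    theta = draw_baseline_proportions(config.pi, config.n_subjects, seed=s_theta)
    mu = apply_effects(theta, truth.beta, x)
    N = draw_library_sizes(config.n_subjects, config.mean_depth, config.sigma_L, seed=s_depth)
    y = draw_counts(mu, N, seed=s_counts)
    return SimulatedDataset(
        x=x,
        N=N,
        y=y,
        truth=truth,
        theta=theta if keep_intermediates else None,
        mu=mu if keep_intermediates else None,
        config=config,
    )


def dataset_diagnostics(y: np.ndarray) -> dict:
    """Per-OTU mean, variance, zero fraction and per-sample library sizes.

    These are the realism diagnostics used to compare a simulated table
    against a real one: library-size distribution, per-OTU zero inflation and
    the mean-variance relationship.
    """
    y = np.asarray(y)
    if y.ndim != 2 or y.size == 0:
        raise ValueError("y must be a non-empty n x J matrix")
    if np.any(y < 0):
        raise ValueError("y must be nonnegative")
    return {
        "otu_mean": y.mean(axis=0),
        "otu_variance": y.var(axis=0, ddof=0),
        "otu_zero_fraction": (y == 0).mean(axis=0),
        "library_sizes": y.sum(axis=1),
        "n_overdispersed": int(np.sum(y.var(axis=0, ddof=0) > y.mean(axis=0))),
    }
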