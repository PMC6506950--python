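"""Simulator inputs: baseline-composition and library-size calibration.

The simulator needs (a) a Dirichlet parameter ``pi`` describing the baseline
community composition and its between-subject variability and (b) a lognormal
model for sequencing depth.  Both can be fitted from a real OTU table with the
estimators here, or generated synthetically so the package runs with no
external data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import gammaln, psi

__all__ = [
    "CompositionTemplate",
    "LibrarySizeModel",
    "fit_dirichlet_multinomial",
    "fit_lognormal",
    "generate_synthetic_pi",
    "generate_dietary_variable",
    "sample_covariate_from_template",
    "dirichlet_multinomial_loglik",
]


@dataclass(frozen=True)
class CompositionTemplate:
    """Dirichlet parameter for baseline compositions: direction x concentration."""

    pi: np.ndarray
    source: str = "synthetic"  # "fitted" | "synthetic"
    otu_ids: tuple = None

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        if np.any(pi <= 0) or not np.all(np.isfinite(pi)):
            raise ValueError("pi entries must be positive and finite")
        object.__setattr__(self, "pi", pi)
        if self.otu_ids is None:
            object.__setattr__(
                self, "otu_ids", tuple(f"OTU{j + 1}" for j in range(pi.size))
            )

    @property
    def concentration(self) -> float:
        """Dirichlet precision (sum of pi); small values mean strong
        between-subject variability in composition."""
        return float(self.pi.sum())

    @property
    def direction(self) -> np.ndarray:
        """Expected composition: pi normalized to the simplex."""
        return self.pi / self.pi.sum()

    def to_tsv(self, path) -> None:
        pd.DataFrame({"otu_id": list(self.otu_ids), "pi": self.pi}).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path, source: str = "fitted") -> "CompositionTemplate":
        df = pd.read_csv(path, sep="\t")
        return cls(
            pi=df["pi"].to_numpy(float),
            source=source,
            otu_ids=tuple(df["otu_id"].astype(str)),
        )


@dataclass(frozen=True)
class LibrarySizeModel:
    """Lognormal model of sequencing depth: log N ~ Normal(mu_L, sigma_L^2)."""

    mu_L: float
    sigma_L: float

    def __post_init__(self) -> None:
        if self.sigma_L < 0:
            raise ValueError("sigma_L must be >= 0")

    @property
    def median_depth(self) -> float:
        return float(np.exp(self.mu_L))


def dirichlet_multinomial_loglik(y: np.ndarray, pi: np.ndarray) -> float:
    """Dirichlet-multinomial log-likelihood, multinomial coefficient omitted."""
    y = np.asarray(y, dtype=float)
    pi = np.asarray(pi, dtype=float)
    N = y.sum(axis=1)
    a0 = pi.sum()
    ll = np.sum(gammaln(a0) - gammaln(N + a0))
    ll += np.sum(gammaln(y + pi) - gammaln(pi))
    return float(ll)


def fit_dirichlet_multinomial(
    y: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 1000,
    return_loglik: bool = False,
):
    """Maximum-likelihood Dirichlet-multinomial fit via fixed-point iteration.

    Uses the digamma fixed-point update

        pi_j <- pi_j * sum_i [psi(y_ij + pi_j) - psi(pi_j)]
                     / sum_i [psi(N_i + pi0) - psi(pi0)],

    a minorize-maximize scheme whose log-likelihood is non-decreasing.
    All-zero OTU columns are dropped with a warning (their pi component is
    not identifiable).  Convergence: max absolute parameter change < ``tol``
    or ``max_iter`` iterations.

    Returns a :class:`CompositionTemplate`; with ``return_loglik`` also the
    per-iteration log-likelihood trace.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 2 or y.shape[0] < 2:
        raise ValueError("need a 2-d count matrix with at least 2 samples")
    if y.shape[1] < 2:
        raise ValueError("need at least 2 OTU columns")
    col_tot = y.sum(axis=0)
    keep = col_tot > 0
    ids = np.array([f"OTU{j + 1}" for j in range(y.shape[1])])
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} all-zero OTU columns "
            "(pi not identifiable)",
            RuntimeWarning,
            stacklevel=2,
        )
        y = y[:, keep]
        ids = ids[keep]

    N = y.sum(axis=1)
    # moment-based initialization: mean proportions scaled by a rough
    # precision from the spread of per-sample proportions
    p = y / N[:, None]
    m = p.mean(axis=0)
    v = p.var(axis=0, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        prec = m * (1 - m) / v - 1.0
    prec = prec[np.isfinite(prec) & (prec > 0)]
    c0 = float(np.median(prec)) if prec.size else 1.0
    pi = np.maximum(m * max(c0, 1.0), 1e-8)

    trace = [dirichlet_multinomial_loglik(y, pi)]
    for _ in range(max_iter):
        a0 = pi.sum()
        num = psi(y + pi).sum(axis=0) - y.shape[0] * psi(pi)
        den = np.sum(psi(N + a0) - psi(a0))
        pi_new = pi * num / den
        pi_new = np.maximum(pi_new, 1e-12)
        trace.append(dirichlet_multinomial_loglik(y, pi_new))
        delta = np.max(np.abs(pi_new - pi))
        pi = pi_new
        if delta < tol:
            break

    template = CompositionTemplate(pi=pi, source="fitted", otu_ids=tuple(ids))
    if return_loglik:
        return template, np.asarray(trace)
    return template


def fit_lognormal(N: np.ndarray) -> LibrarySizeModel:
    """Lognormal MLE for library sizes (n-denominator for the sd)."""
    N = np.asarray(N, dtype=float)
    if np.any(N <= 0):
        raise ValueError("library sizes must be > 0")
    logN = np.log(N)
    mu = float(logN.mean())
    sigma = float(np.sqrt(np.mean((logN - mu) ** 2)))
    return LibrarySizeModel(mu_L=mu, sigma_L=sigma)


def generate_synthetic_pi(
    J: int,
    concentration: float = 50.0,
    tail_shape: float = 2.0,
    seed=0,
) -> CompositionTemplate:
    """Heavy-tailed synthetic baseline composition.

    The direction is drawn from normalized lognormal weights with log-sd
    ``tail_shape``, giving the few-dominant / many-rare structure of real
    stool communities, then scaled by ``concentration`` (the Dirichlet
    precision).  The defaults — precision 50, tail_shape 2 — match the
    overdispersion (theta about 0.02) and dominance typical of
    Dirichlet-multinomial fits to stool 16S tables.
    """
    if J < 2:
        raise ValueError("J must be >= 2")
    if concentration <= 0 or tail_shape <= 0:
        raise ValueError("concentration and tail_shape must be > 0")
    rng = np.random.default_rng(seed)
    w = np.exp(tail_shape * rng.standard_normal(J))
    direction = w / w.sum()
    return CompositionTemplate(pi=direction * concentration, source="synthetic")


def _sinh_arcsinh(z: np.ndarray, eps: float) -> np.ndarray:
    """Skewing transform sinh((asinh(z) + eps) / delta).

    The tail-weight parameter is tied to the skew parameter,
    delta = 1 / (1 + eps/2): raising eps both shifts and fattens the upper
    tail, so the population skewness of the transformed standard normal is
    monotone in eps and unbounded (the location parameter alone saturates
    near 1.44).
    """
    delta = 1.0 / (1.0 + abs(eps) / 2.0)
    return np.sinh((np.arcsinh(z) + eps) / delta)


@lru_cache(maxsize=256)
def _sinh_arcsinh_eps(skew_target: float) -> float:
    """Skew parameter whose population skewness equals ``skew_target``
    (Gauss-Hermite quadrature + root finding)."""
    if skew_target == 0.0:
        return 0.0
    sign = 1.0 if skew_target > 0 else -1.0
    target = abs(skew_target)
    t, w = np.polynomial.hermite_e.hermegauss(151)
    w = w / w.sum()

    def pop_skew(eps: float) -> float:
        y = _sinh_arcsinh(t, eps)
        m1 = np.sum(w * y)
        m2 = np.sum(w * (y - m1) ** 2)
        m3 = np.sum(w * (y - m1) ** 3)
        return m3 / m2 ** 1.5

    hi = 0.1
    while pop_skew(hi) < target:
        hi *= 2.0
        if hi > 64:
            raise ValueError("skew_target out of the attainable range")
    eps = optimize.brentq(lambda e: pop_skew(e) - target, 0.0, hi, xtol=1e-10)
    return sign * eps


def generate_dietary_variable(
    n: int,
    skew_target: float = 0.0,
    seed=0,
    zero_inflation: float = 0.0,
) -> np.ndarray:
    """Standardized covariate with controllable skewness.

    Draws from a sinh-arcsinh-transformed normal (see :func:`_sinh_arcsinh`)
    with the skew parameter calibrated so the population skewness equals
    ``skew_target``, then
    standardizes to sample mean 0 and sd 1 — emulating food-frequency items
    whose intake distributions range from symmetric to strongly
    right-skewed.  With ``zero_inflation`` q > 0, a fraction q of subjects is
    set to zero intake (exp-transformed nonzero part) before standardizing,
    mimicking items many subjects never consume.
    """
    if n < 3:
        raise ValueError("n must be >= 3 (skewness undefined below that)")
    if not 0.0 <= zero_inflation < 1.0:
        raise ValueError("zero_inflation must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    eps = _sinh_arcsinh_eps(float(skew_target))
    z = rng.standard_normal(n)
    x = _sinh_arcsinh(z, eps)
    if zero_inflation > 0:
        x = np.exp(x)
        x[rng.random(n) < zero_inflation] = 0.0
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("degenerate covariate draw (zero variance)")
    return (x - x.mean()) / sd


def sample_covariate_from_template(
    template, column, n: int, seed=0
) -> np.ndarray:
    """Resample a template covariate column with replacement, restandardized."""
    if isinstance(template, (str, Path)):
        template = pd.read_csv(template, sep="\t")
    if column not in template.columns:
        raise KeyError(f"column {column!r} not in template")
    vals = pd.to_numeric(template[column], errors="raise").to_numpy(float)
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    x = rng.choice(vals, size=n, replace=True)
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("sampled covariate is constant; cannot standardize")
    return (x - x.mean()) / sd
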