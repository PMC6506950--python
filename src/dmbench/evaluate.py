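"""Scoring against spike-in truth: confusion counts, rates, consensus sets.

Per simulation and method, significant calls (BH-adjusted q < alpha, strict)
are cross-tabulated against the planted truth eta to give TP/FP/TN/FN, from
which

    true positive rate  = TP / (TP + FN)
    false positive rate = FP / (TN + FP)
    error probability   = FP / (TP + FP)

The error probability is the realized false-discovery proportion of one
simulation; it is undefined (not zero) when a method calls nothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .base import METHODS

__all__ = [
    "Confusion",
    "PerformanceMetrics",
    "BenchmarkSummary",
    "bh_adjust",
    "classify",
    "compute_metrics",
    "consensus_overlap",
    "sample_skewness",
    "summarize_benchmark",
]


@dataclass(frozen=True)
class Confusion:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def n_tested(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class PerformanceMetrics:
    tpr: float
    fpr: float
    error_probability: float  # NaN when undefined (no calls)
    method: str = ""
    simulation_id: int = -1
    skewness: float = np.nan


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify(q: np.ndarray, eta: np.ndarray, alpha: float = 0.05) -> Confusion:
    """Cross-tabulate significant calls (q < alpha, strict) against truth."""
    q = np.asarray(q, dtype=float)
    eta = np.asarray(eta)
    if q.size != eta.size:
        raise ValueError("q and eta must have equal length")
    sig = q < alpha
    pos = eta == 1
    return Confusion(
        tp=int(np.sum(sig & pos)),
        fp=int(np.sum(sig & ~pos)),
        tn=int(np.sum(~sig & ~pos)),
        fn=int(np.sum(~sig & pos)),
    )


def compute_metrics(c: Confusion, **tags) -> PerformanceMetrics:
    """Rates from a confusion table; zero denominators give NaN."""
    tpr = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else np.nan
    fpr = c.fp / (c.tn + c.fp) if (c.tn + c.fp) > 0 else np.nan
    err = c.fp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else np.nan
    return PerformanceMetrics(tpr=tpr, fpr=fpr, error_probability=err, **tags)


def consensus_overlap(
    results: pd.DataFrame,
    truth: Optional[Dict[str, int]] = None,
    alpha: float = 0.05,
    methods=METHODS,
) -> dict:
    """Set algebra over the per-method significant sets.

    Returns the per-method sets, all pairwise and the four-way intersection
    counts, per-method uniquely-significant counts (member of exactly one
    method's set), and — when ``truth`` (otu_id -> eta) is given — the
    confusion of the overlap set against truth over all tested OTUs.
    """
    present = set(results["method"].unique())
    missing = [m for m in methods if m not in present]
    if missing:
        raise ValueError(f"results table lacks method(s): {missing}")
    sets = {
        m: set(
            results.loc[(results["method"] == m) & (results["qvalue"] < alpha), "otu_id"]
        )
        for m in methods
    }
    overlap = set.intersection(*sets.values())
    union_counts: Dict[str, int] = {}
    for m in methods:
        others = set().union(*(sets[o] for o in methods if o != m))
        union_counts[m] = len(sets[m] - others)
    pairwise = {
        (a, b): len(sets[a] & sets[b]) for a, b in combinations(methods, 2)
    }
    out = {
        "sets": sets,
        "overlap": overlap,
        "pairwise_counts": pairwise,
        "overlap_count": len(overlap),
        "unique_counts": union_counts,
    }
    if truth is not None:
        tested = results["otu_id"].unique()
        eta = np.array([truth[t] for t in tested])
        sig = np.array([t in overlap for t in tested])
        out["overlap_confusion"] = Confusion(
            tp=int(np.sum(sig & (eta == 1))),
            fp=int(np.sum(sig & (eta == 0))),
            tn=int(np.sum(~sig & (eta == 0))),
            fn=int(np.sum(~sig & (eta == 1))),
        )
    return out


def sample_skewness(x: np.ndarray) -> float:
    """Adjusted Fisher-Pearson sample skewness; NaN for a constant vector."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        return np.nan
    return float(stats.skew(x, bias=False))


@dataclass(frozen=True)
class BenchmarkSummary:
    """Cross-simulation summary of the method comparison."""

    per_simulation: pd.DataFrame  # simulation_id, method, tp..fn, rates, skewness
    medians: pd.DataFrame  # method x {tpr, fpr, error_probability}
    lowest_error_counts: Dict[str, int]
    frac_error_below: Dict[str, float]  # fraction of sims with error < 0.05
    overlap_frac_below: float
    n_simulations: int


def summarize_benchmark(
    per_sim: pd.DataFrame, threshold: float = 0.05
) -> BenchmarkSummary:
    """Aggregate per-simulation metrics across the benchmark.

    Medians and the "< threshold" fractions exclude undefined (NaN) error
    probabilities; the strictly-lowest-error count credits no method in case
    of a tie.  ``per_sim`` must have columns simulation_id, method, tpr,
    fpr, error_probability (the ``overlap`` pseudo-method row is optional
    and excluded from the ranking).
    """
    if per_sim.empty:
        raise ValueError("no simulations to summarize")
    methods = [m for m in per_sim["method"].unique() if m != "overlap"]
    med = (
        per_sim[per_sim["method"].isin(methods)]
        .groupby("method")[["tpr", "fpr", "error_probability"]]
        .median()
        .reindex(methods)
    )

    lowest = {m: 0 for m in methods}
    for _, g in per_sim[per_sim["method"].isin(methods)].groupby("simulation_id"):
        errs = g.set_index("method")["error_probability"].dropna()
        if errs.empty:
            continue
        mn = errs.min()
        winners = errs.index[errs == mn]
        if len(winners) == 1:
            lowest[winners[0]] += 1

    frac = {}
    for m in methods:
        e = per_sim.loc[per_sim["method"] == m, "error_probability"].dropna()
        frac[m] = float((e < threshold).mean()) if len(e) else np.nan

    ov = per_sim.loc[per_sim["method"] == "overlap", "error_probability"].dropna()
    ov_frac = float((ov < threshold).mean()) if len(ov) else np.nan

    return BenchmarkSummary(
        per_simulation=per_sim,
        medians=med,
        lowest_error_counts=lowest,
        frac_error_below=frac,
        overlap_frac_below=ov_frac,
        n_simulations=int(per_sim["simulation_id"].nunique()),
    )
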