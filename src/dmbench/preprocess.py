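"""Shared preprocessing for the association methods: OTU filtering,
log-cpm transformation and cumulative sum scaling (CSS) normalization."""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["filter_otus", "logcpm_transform", "css_scaling"]


def filter_otus(
    y: np.ndarray, min_total: int = 10, min_prevalence: float = 0.01
):
    """Remove rare OTUs before testing.

    Keeps OTUs with at least ``min_total`` reads in total AND present
    (count > 0) in at least ``min_prevalence`` of samples; "fewer than" is
    strict, so an OTU exactly at either boundary is kept.

    Returns ``(filtered_matrix, kept_indices)``.
    """
    y = np.asarray(y)
    if y.ndim != 2:
        raise ValueError("y must be 2-d (samples x OTUs)")
    if np.any(y < 0):
        raise ValueError("counts must be nonnegative")
    total = y.sum(axis=0)
    prevalence = (y > 0).mean(axis=0)
    keep = (total >= min_total) & (prevalence >= min_prevalence)
    return y[:, keep], np.flatnonzero(keep)


def logcpm_transform(y: np.ndarray, N: np.ndarray) -> np.ndarray:
    """log2 counts per million: log2((y + 0.5) / (N + 1) * 1e6)."""
    y = np.asarray(y, dtype=float)
    N = np.asarray(N, dtype=float)
    if np.any(N <= 0):
        raise ValueError("library sizes must be > 0")
    if y.ndim == 2:
        N = N[:, None]
    return np.log2((y + 0.5) / (N + 1.0) * 1e6)


def _css_factor(row: np.ndarray, percentile: float) -> float:
    pos = row[row > 0]
    q = np.quantile(pos, percentile)  # linear interpolation (R type 7)
    return float(row[row <= q].sum())


def _auto_percentile(y: np.ndarray, rel: float = 0.1, floor: float = 0.5) -> float:
    """Instability criterion for the CSS quantile.

    For each candidate percentile, measure the median absolute deviation of
    per-sample quantiles of positive counts from the across-sample reference
    (median) quantile; choose the smallest percentile at which the relative
    change of this deviation between neighboring candidates exceeds ``rel``,
    floored at ``floor``.
    """
    grid = np.arange(0.05, 1.0, 0.01)
    qs = np.stack(
        [np.quantile(row[row > 0], grid) for row in y]
    )  # samples x grid
    ref = np.median(qs, axis=0)
    dev = np.median(np.abs(qs - ref), axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        relchange = np.abs(np.diff(dev)) / np.where(dev[1:] > 0, dev[1:], np.nan)
    unstable = np.flatnonzero(relchange > rel)
    p = grid[unstable[0]] if unstable.size else grid[-1]
    return float(max(p, floor))


def css_scaling(y: np.ndarray, percentile="auto"):
    """Cumulative-sum-scaling normalization.

    The per-sample scaling factor is the sum of that sample's counts that do
    not exceed its own ``percentile`` quantile of positive counts; normalized
    values are ``y / factor * 1000``.  ``percentile="auto"`` selects the
    quantile by the instability criterion (floor 0.5).

    Returns ``(factors, normalized_matrix)``.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 2:
        raise ValueError("y must be 2-d (samples x OTUs)")
    zero_rows = np.flatnonzero(y.sum(axis=1) == 0)
    if zero_rows.size:
        raise ValueError(f"sample(s) {zero_rows.tolist()} have no counts; cannot scale")
    if percentile == "auto":
        percentile = _auto_percentile(y)
    elif not 0.0 < float(percentile) <= 1.0:
        raise ValueError("percentile must lie in (0, 1]")
    factors = np.array([_css_factor(row, percentile) for row in y])
    if np.any(factors == 0):
        warnings.warn("zero CSS factor; falling back to library size", RuntimeWarning)
        bad = factors == 0
        factors[bad] = y[bad].sum(axis=1)
    return factors, y / factors[:, None] * 1000.0
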