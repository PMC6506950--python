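"""Benchmark summary figures (TPR/FPR clouds, error-probability histograms,
uniquely-significant counts)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

_COLORS = {"poisson": "#d62728", "negbin": "#1f77b4", "voom_lm": "#2ca02c",
           "zig": "#9467bd", "overlap": "#7f7f7f"}


def tpr_fpr_scatter(per_sim, ax=None):
    """One dot per simulation and method in TPR-vs-FPR space."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for m, g in per_sim[per_sim["method"] != "overlap"].groupby("method"):
        ax.scatter(g["fpr"], g["tpr"], s=12, alpha=0.6, label=m,
                   color=_COLORS.get(m))
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(fontsize=8)
    return ax


def error_probability_hist(per_sim, ax=None, bins=20):
    """Distribution of per-simulation error probabilities, overlap included."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for m, g in per_sim.groupby("method"):
        ax.hist(g["error_probability"].dropna(), bins=bins, histtype="step",
                label=m, color=_COLORS.get(m))
    ax.axvline(0.05, ls="--", lw=0.8, color="k")
    ax.set_xlabel("error probability")
    ax.set_ylabel("simulations")
    ax.legend(fontsize=8)
    return ax


def unique_counts_lines(per_sim, ax=None):
    """Uniquely-significant associations per simulation and method."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    sub = per_sim[per_sim["method"] != "overlap"].dropna(subset=["n_unique"])
    for m, g in sub.groupby("method"):
        g = g.sort_values("simulation_id")
        ax.plot(g["simulation_id"], g["n_unique"], label=m, lw=1,
                color=_COLORS.get(m))
    ax.set_xlabel("simulation")
    ax.set_ylabel("uniquely significant OTUs")
    ax.legend(fontsize=8)
    return ax


def skewness_vs_error(per_sim, ax=None):
    """Realized covariate skewness against per-method error probability."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for m, g in per_sim[per_sim["method"] != "overlap"].groupby("method"):
        ax.scatter(g["skewness"], g["error_probability"], s=12, alpha=0.6,
                   label=m, color=_COLORS.get(m))
    ax.set_xlabel("covariate skewness")
    ax.set_ylabel("error probability")
    ax.legend(fontsize=8)
    return ax


def save_report(per_sim, outdir):
    """Write the four standard figures as PNGs under ``outdir``."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, fn in [
        ("tpr_vs_fpr.png", tpr_fpr_scatter),
        ("error_probability_hist.png", error_probability_hist),
        ("unique_counts.png", unique_counts_lines),
        ("skewness_vs_error.png", skewness_vs_error),
    ]:
        ax = fn(per_sim)
        ax.figure.tight_layout()
        ax.figure.savefig(outdir / name, dpi=150)
        plt.close(ax.figure)
    return outdir
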