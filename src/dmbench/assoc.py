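"""Run the four association methods on a simulated (or real) dataset.

The methods mirror four families in routine use for count-based
differential-abundance and association testing:

- ``poisson``: Poisson GLM with log(total counts) offset, Wald z;
- ``negbin``: negative-binomial GLM with empirical-Bayes tagwise
  dispersions, log-total offset, likelihood-ratio test;
- ``voom_lm``: log-cpm + mean-variance precision weights + moderated t;
- ``zig``: CSS normalization + zero-inflated Gaussian EM + moderated t.

All p-values are Benjamini-Hochberg adjusted within method.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .base import METHODS
from .evaluate import bh_adjust
from .glm import estimate_dispersions, fit_glm_batch
from .preprocess import css_scaling, filter_otus, logcpm_transform
from .voom import moderated_t, squeeze_var, voom_weights, wls_batch
from .zig import zig_em_batch

__all__ = ["run_all_methods", "METHODS"]


def _finite_or(v, default):
    v = np.asarray(v, dtype=float)
    return np.where(np.isfinite(v), v, default)


def run_all_methods(
    dataset,
    methods=METHODS,
    min_total: int = 10,
    min_prevalence: float = 0.01,
    prior_df: float = 10.0,
    css_percentile="auto",
    zig_max_iter: int = 30,
    otu_ids=None,
) -> pd.DataFrame:
    """Test every kept OTU against the covariate with each method.

    ``dataset`` is a :class:`~dmbench.simgen.SimulatedDataset` or any object
    with ``y`` (n x J counts) and ``x`` attributes.  Returns a long table
    with one row per (otu, method): otu_id, method, coef, se, stat, pvalue,
    qvalue, converged, and the integer column index ``otu_index`` into the
    original matrix (so results can be matched to per-OTU truth).
    """
    y_full = np.asarray(dataset.y)
    x = np.asarray(dataset.x, dtype=float)
    if otu_ids is None:
        otu_ids = (
            dataset.otu_ids
            if hasattr(dataset, "otu_ids")
            else np.array([f"OTU{j + 1}" for j in range(y_full.shape[1])])
        )
    otu_ids = np.asarray(otu_ids)

    y, kept = filter_otus(y_full, min_total=min_total, min_prevalence=min_prevalence)
    ids = otu_ids[kept]
    n, J = y.shape
    if J == 0:
        raise ValueError("no OTUs pass the filter")
    # total counts of the analyzed table are the offset everywhere
    N = y.sum(axis=1)
    offset = np.log(N)
    y = y.astype(float)

    frames = []

    if "poisson" in methods:
        fit = fit_glm_batch(y, x, offset, alpha=0.0)
        b1, se = fit["coef"][1], fit["se1"]
        ok = fit["converged"] & np.isfinite(se) & (se > 0)
        z = np.where(ok, b1 / np.where(se > 0, se, 1.0), np.nan)
        p = np.where(ok, 2.0 * stats.norm.sf(np.abs(z)), 1.0)
        frames.append(_frame(ids, kept, "poisson", b1, se, z, p, ok))

    if "negbin" in methods:
        disp = estimate_dispersions(y, x, N, prior_df=prior_df)
        full = fit_glm_batch(y, x, offset, alpha=disp)
        nullf = fit_glm_batch(y, x, offset, alpha=disp, null=True)
        dev = np.maximum(2.0 * (full["loglik"] - nullf["loglik"]), 0.0)
        ok = full["converged"]
        p = np.where(ok, stats.chi2.sf(dev, 1), 1.0)
        frames.append(_frame(ids, kept, "negbin", full["coef"][1], full["se1"], dev, p, ok))

    if "voom_lm" in methods:
        z_mat = logcpm_transform(y, N)
        w = voom_weights(z_mat, x, N)
        b0, b1, rss, inv11 = wls_batch(z_mat, x, w)
        df = n - 2
        s2 = rss / df
        se_unit = np.sqrt(inv11)
        ok = np.isfinite(b1) & np.isfinite(se_unit) & (se_unit > 0)
        d0, s02 = squeeze_var(s2[ok], df)
        t, p, post, _ = moderated_t(
            _finite_or(b1, 0.0), _finite_or(se_unit, 1.0), _finite_or(s2, s02), df, d0, s02
        )
        p = np.where(ok, p, 1.0)
        frames.append(
            _frame(ids, kept, "voom_lm", b1, se_unit * np.sqrt(post), t, p, ok)
        )

    if "zig" in methods:
        # the zero-inflated Gaussian as the field's reference implementation
        # runs it: raw log2 counts, CSS scaling factor as a mean covariate,
        # and the weighted fit moderated on the FULL residual df (n - p) —
        # see dmbench.zig for why this makes the test anticonservative
        factors, _ = css_scaling(y, percentile=css_percentile)
        z_mat = np.log2(y + 1.0)
        css_cov = np.log2(factors / 1000.0 + 1.0)
        fit = zig_em_batch(z_mat, x, offset, extra=css_cov, max_iter=zig_max_iter)
        b1 = fit["coef"][1]
        inv11 = fit["inv11"]
        ok = np.isfinite(b1) & np.isfinite(inv11) & (inv11 > 0)
        se_unit = np.sqrt(np.where(ok, inv11, np.nan))
        df_full = float(n - fit["n_features"])
        s2 = fit["rss"] / df_full
        d0, s02 = squeeze_var(s2[ok], df_full)
        t, p, post, _ = moderated_t(
            _finite_or(b1, 0.0), _finite_or(se_unit, 1.0),
            _finite_or(s2, s02), df_full, d0, s02,
        )
        p = np.where(ok, p, 1.0)
        frames.append(
            _frame(ids, kept, "zig", b1, se_unit * np.sqrt(post), t, p,
                   ok & fit["converged"])
        )

    out = pd.concat(frames, ignore_index=True)
    out["qvalue"] = np.nan
    for m in out["method"].unique():
        sel = out["method"] == m
        out.loc[sel, "qvalue"] = bh_adjust(out.loc[sel, "pvalue"].to_numpy())
    return out


def _frame(ids, kept, method, coef, se, stat, p, ok) -> pd.DataFrame:
    p = np.clip(np.asarray(p, dtype=float), 0.0, 1.0)
    return pd.DataFrame(
        {
            "otu_id": ids,
            "otu_index": kept,
            "method": method,
            "coef": np.asarray(coef, dtype=float),
            "se": np.asarray(se, dtype=float),
            "stat": np.asarray(stat, dtype=float),
            "pvalue": np.where(np.asarray(ok, bool), p, 1.0),
            "converged": np.asarray(ok, bool),
        }
    )
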