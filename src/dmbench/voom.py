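"""Precision-weighted log-cpm regression with moderated t statistics.

Counts are transformed to log2 counts-per-million; an observation-level
precision weight is predicted from the empirical mean-variance trend
(lowess of sqrt residual sd against average log count), and each OTU is fit
by weighted least squares.  Residual variances are squeezed across OTUs by
empirical Bayes (scaled inverse chi-square prior fit by moment matching on
log s^2), and the slope is tested with a moderated t on d0 + d degrees of
freedom.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats
from scipy.special import polygamma, psi
from statsmodels.nonparametric.smoothers_lowess import lowess

from .base import AssocResult

__all__ = ["voom_weights", "weighted_lm_association", "squeeze_var", "wls_batch"]


def wls_batch(Z: np.ndarray, x: np.ndarray, W: np.ndarray = None):
    """Weighted least squares z = b0 + b1 x for every OTU column.

    ``W`` is an n x J weight matrix (or None for OLS).  Returns b0, b1,
    weighted residual sum of squares, and the (1,1) element of (X'WX)^-1.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    x = np.asarray(x, dtype=float)
    n, J = Z.shape
    W = np.ones_like(Z) if W is None else np.asarray(W, dtype=float)
    if W.ndim == 1:
        W = np.broadcast_to(W[:, None], Z.shape)
    s00 = W.sum(axis=0)
    s01 = x @ W
    s11 = (x * x) @ W
    t0 = np.sum(W * Z, axis=0)
    t1 = np.sum(W * (x[:, None] * Z), axis=0)
    det = s00 * s11 - s01 * s01
    ok = det > 1e-12 * np.maximum(s00 * s11, 1e-300)
    det = np.where(ok, det, np.nan)
    b1 = (s00 * t1 - s01 * t0) / det
    b0 = (t0 - s01 * b1) / s00
    resid = Z - b0[None, :] - np.outer(x, b1)
    rss = np.sum(W * resid * resid, axis=0)
    inv11 = s00 / det
    return b0, b1, rss, inv11


def voom_weights(logcpm: np.ndarray, x: np.ndarray, N: np.ndarray) -> np.ndarray:
    """Observation-level precision weights from the mean-variance trend.

    Per-OTU linear fits give residual sds; a lowess trend of sqrt(sd) against
    average log2 count is interpolated at each observation's fitted log2
    count, and the weight is the predicted sqrt-sd to the power -4 (i.e. the
    reciprocal of the predicted variance).
    """
    logcpm = np.asarray(logcpm, dtype=float)
    x = np.asarray(x, dtype=float)
    N = np.asarray(N, dtype=float)
    n, J = logcpm.shape
    if J < 10:
        raise ValueError("need at least 10 OTUs to estimate the trend")

    b0, b1, rss, _ = wls_batch(logcpm, x)
    s = np.sqrt(rss / (n - 2))
    sy = np.sqrt(s)  # sqrt residual sd
    # average log2 count corresponding to each OTU's mean log-cpm
    log2_depth = np.mean(np.log2(N + 1.0))
    sx = logcpm.mean(axis=0) + log2_depth - np.log2(1e6)

    fit = lowess(sy, sx, frac=0.5)
    xs, ys = fit[:, 0], fit[:, 1]
    if np.ptp(ys) < 1e-12 or np.ptp(xs) < 1e-12:
        warnings.warn("degenerate mean-variance trend; uniform weights", RuntimeWarning)
        return np.ones_like(logcpm)

    fitted = b0[None, :] + np.outer(x, b1)  # fitted log-cpm
    lam = fitted + np.log2(N + 1.0)[:, None] - np.log2(1e6)
    pred = np.interp(lam, xs, ys)  # clamped at trend ends
    pred = np.maximum(pred, 1e-6)
    return pred ** -4


def squeeze_var(s2: np.ndarray, df):
    """Empirical-Bayes hyperparameters (d0, s0^2) for residual variances.

    Moment matching on log s^2 under the scaled-F model of the variances:
    d0 solves trigamma(d0/2) = var(log s2) - mean trigamma(df/2); if the
    right side is <= 0 the prior is infinitely informative (d0 = inf).
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        return np.inf, float(np.nanmedian(np.where(ok, s2, np.nan)))
    z = np.log(s2[ok])
    e = z - psi(df[ok] / 2) + np.log(df[ok] / 2)
    evar = np.var(e, ddof=1) - np.mean(polygamma(1, df[ok] / 2))
    if evar <= 0:
        return np.inf, float(np.exp(np.mean(e)))
    d0 = 2.0 * _trigamma_inverse(evar)
    s02 = float(np.exp(np.mean(e) + psi(d0 / 2) - np.log(d0 / 2)))
    return float(d0), s02


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def moderated_t(b1, se_unit, s2, df, d0, s02):
    """Moderated t statistics given EB hyperparameters.

    ``se_unit`` is the unscaled standard error sqrt((X'WX)^-1_11); the
    posterior variance replaces s^2 in the usual t.
    """
    d0 = np.inf if d0 is None else d0
    if np.isinf(d0):
        post = np.full_like(np.asarray(s2, float), s02)
    else:
        post = (d0 * s02 + df * s2) / (d0 + df)
    t = b1 / (se_unit * np.sqrt(post))
    df_tot = np.minimum(d0 + df, 1e300)
    p = 2.0 * stats.t.sf(np.abs(t), df_tot)
    return t, p, post, df_tot


def weighted_lm_association(
    z_col, x, w, moderation=None, otu_id: str = "OTU1", method: str = "voom_lm"
) -> AssocResult:
    """Weighted linear regression test of one OTU.

    ``moderation`` is None (plain t on n-2 df) or a (d0, s0^2) pair from
    :func:`squeeze_var` fitted across OTUs.
    """
    z_col = np.asarray(z_col, dtype=float)
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be > 0")
    if np.ptp(x) == 0:
        return AssocResult(otu_id, method, 0.0, np.nan, np.nan, 1.0, converged=False)
    n = z_col.size
    b0, b1, rss, inv11 = wls_batch(z_col, x, w)
    if not np.isfinite(b1[0]):
        return AssocResult(otu_id, method, 0.0, np.nan, np.nan, 1.0, converged=False)
    df = n - 2
    s2 = rss[0] / df
    se_unit = np.sqrt(inv11[0])
    if moderation is None:
        d0, s02 = 0.0, 0.0
        post = s2 if s2 > 0 else 1e-300
        t = b1[0] / (se_unit * np.sqrt(post))
        p = 2.0 * stats.t.sf(abs(t), df)
        return AssocResult(otu_id, method, float(b1[0]), float(se_unit * np.sqrt(post)), float(t), float(min(p, 1.0)))
    d0, s02 = moderation
    t, p, post, _ = moderated_t(b1[0], se_unit, s2, df, d0, s02)
    return AssocResult(
        otu_id, method, float(b1[0]), float(se_unit * np.sqrt(post)), float(t), float(min(p, 1.0))
    )
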