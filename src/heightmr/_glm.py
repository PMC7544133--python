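"""Vectorized marginal regressions used by the synthetic-data generator.

Per-variant GWAS scans need thousands of tiny regressions (one per variant);
these closed-form/Newton routines run them as batched array operations. They
are internal: user-facing model fits go through statsmodels.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def marginal_linear(G: np.ndarray, y: np.ndarray):
    """Simple linear regression of y on each column of G.

    Returns (beta, se, pvalue) arrays of length G.shape[1]. Monomorphic
    columns get beta 0 and se inf.
    """
    n = len(y)
    gbar = G.mean(axis=0)
    ybar = y.mean()
    gc = G - gbar
    yc = y - ybar
    sgg = np.einsum("ij,ij->j", gc, gc)
    sgy = yc @ gc
    mono = sgg == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(mono, 0.0, sgy / np.where(mono, 1.0, sgg))
        rss = np.sum(yc ** 2) - beta * sgy
        sigma2 = rss / (n - 2)
        se = np.sqrt(np.where(mono, np.inf, sigma2 / np.where(mono, 1.0, sgg)))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(beta / se)
    p = 2.0 * stats.t.sf(t, n - 2)
    p = np.where(mono, 1.0, np.clip(p, 1e-300, 1.0))
    return beta, se, p


def marginal_logistic(G: np.ndarray, y: np.ndarray, max_iter: int = 25,
                      tol: float = 1e-8):
    """Univariate logistic regression y ~ 1 + g for each column of G.

    Batched Newton–Raphson over all variants simultaneously; the 2×2 update is
    solved in closed form. Returns (beta, se, pvalue). Monomorphic columns get
    beta 0 and se inf.
    """
    n, m = G.shape
    mono = G.std(axis=0) == 0
    ybar = y.mean()
    a = np.full(m, np.log(ybar / (1.0 - ybar)))  # intercepts
    b = np.zeros(m)                              # slopes
    active = ~mono
    for _ in range(max_iter):
        eta = a[None, :] + G * b[None, :]
        mu = 1.0 / (1.0 + np.exp(-eta))
        r = y[:, None] - mu
        wv = mu * (1.0 - mu)
        g0 = r.sum(axis=0)
        g1 = np.einsum("ij,ij->j", r, G)
        h00 = wv.sum(axis=0)
        h01 = np.einsum("ij,ij->j", wv, G)
        h11 = np.einsum("ij,ij,ij->j", wv, G, G)
        det = h00 * h11 - h01 ** 2
        det = np.where(det <= 0, np.nan, det)
        da = (h11 * g0 - h01 * g1) / det
        db = (-h01 * g0 + h00 * g1) / det
        da = np.where(active & np.isfinite(da), da, 0.0)
        db = np.where(active & np.isfinite(db), db, 0.0)
        a += da
        b += db
        step = np.maximum(np.abs(da), np.abs(db))
        active = active & (step > tol)
        if not active.any():
            break
    # SE from the final observed information
    eta = a[None, :] + G * b[None, :]
    mu = 1.0 / (1.0 + np.exp(-eta))
    wv = mu * (1.0 - mu)
    h00 = wv.sum(axis=0)
    h01 = np.einsum("ij,ij->j", wv, G)
    h11 = np.einsum("ij,ij,ij->j", wv, G, G)
    det = h00 * h11 - h01 ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(np.where(mono | (det <= 0), np.inf,
                              h00 / np.where(det <= 0, 1.0, det)))
    b = np.where(mono, 0.0, b)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.abs(b / se)
    p = np.where(mono, 1.0, np.clip(2.0 * stats.norm.sf(z), 1e-300, 1.0))
    return b, se, p
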