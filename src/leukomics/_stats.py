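"""Small statistical helpers shared across modules.

Correlation p-values follow the t-distribution transform used by R's
``cor.test``: t = r*sqrt(n-2)/sqrt(1-r^2) on n-2 degrees of freedom,
two-sided.  Fisher's z = atanh(r) with variance 1/(n-3) is used wherever
correlations are compared on a common scale.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

# |r| = 1 maps to an infinite Fisher z; clip just inside the boundary.
_R_CLIP = 1.0 - 1e-12


def corr_pvalue(r: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Two-sided p-value for a correlation via the t transform (df = n-2)."""
    r = np.asarray(r, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(n - 2.0) / np.sqrt(1.0 - r * r)
        p = 2.0 * stats.t.sf(np.abs(t), n - 2.0)
    # |r| == 1 gives t = inf -> p = 0; undefined for n <= 2
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    p = np.where(n <= 2, np.nan, p)
    return p


def fisher_z(r: np.ndarray, clip: bool = True) -> np.ndarray:
    """atanh transform; |r|=1 clipped just inside (-1, 1) when ``clip``."""
    r = np.asarray(r, dtype=float)
    if clip:
        r = np.clip(r, -_R_CLIP, _R_CLIP)
    return np.arctanh(r)


def fisher_z_difference(r_a, n_a, r_b, n_b):
    """Standardized difference of two independent correlations.

    z = (atanh(r_a) - atanh(r_b)) / sqrt(1/(n_a-3) + 1/(n_b-3)),
    approximately standard normal under r_a = r_b.
    """
    za, zb = fisher_z(r_a), fisher_z(r_b)
    n_a = np.asarray(n_a, dtype=float)
    n_b = np.asarray(n_b, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(1.0 / (n_a - 3.0) + 1.0 / (n_b - 3.0))
        z = (za - zb) / se
    return np.where((n_a > 3) & (n_b > 3), z, np.nan)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values; NaNs are passed through."""
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def pairwise_complete_corr(x: np.ndarray, y: np.ndarray, method: str = "pearson",
                           min_n: int = 2) -> tuple[float, int]:
    """Correlation of two 1-D arrays over jointly finite entries.

    Returns (r, n_pairs); r is NaN when fewer than ``min_n`` complete pairs
    remain or either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < max(min_n, 2):
        return np.nan, n
    xs, ys = x[ok], y[ok]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return np.nan, n
    if method == "spearman":
        r = stats.spearmanr(xs, ys).statistic
    elif method == "pearson":
        r = stats.pearsonr(xs, ys).statistic
    else:
        raise ValueError(f"unknown correlation method: {method!r}")
    return float(r), n


def columnwise_corr_with_vector(mat: np.ndarray, vec: np.ndarray,
                                min_n: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r of each row of ``mat`` (features x samples) with ``vec``.

    Pairwise-complete over finite entries; vectorized over features.
    Returns (r, n) arrays of length mat.shape[0].
    """
    mat = np.asarray(mat, dtype=float)
    vec = np.asarray(vec, dtype=float)
    ok = np.isfinite(mat) & np.isfinite(vec)[None, :]
    n = ok.sum(axis=1).astype(float)
    xm = np.where(ok, mat, 0.0)
    ym = np.where(ok, vec[None, :], 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mx = xm.sum(axis=1) / n
        my = ym.sum(axis=1) / n
        xc = np.where(ok, mat - mx[:, None], 0.0)
        yc = np.where(ok, vec[None, :] - my[:, None], 0.0)
        cov = (xc * yc).sum(axis=1)
        vx = (xc * xc).sum(axis=1)
        vy = (yc * yc).sum(axis=1)
        r = cov / np.sqrt(vx * vy)
    r = np.where((n >= max(min_n, 2)) & (vx > 0) & (vy > 0), r, np.nan)
    return r, n.astype(int)
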