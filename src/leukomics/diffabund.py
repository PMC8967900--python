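"""PSM-moderated differential abundance and preranked gene-set enrichment.

The moderated test follows the empirical-Bayes variance-moderation idea used
for isobaric-labelling proteomics: per-protein residual variance (pooled
across the contrast groups plus an optional "other" stratum) is shrunk
toward a smooth trend of log variance on log minimum PSM count, with the
prior degrees of freedom estimated from the scatter of log variances around
the trend via the method of moments on the log-F distribution.  The
moderated t uses the augmented degrees of freedom.  This re-implements the
documented core idea of variance moderation, not any particular package's
internals.

Preranked GSEA is the weighted Kolmogorov-Smirnov running-sum statistic with
gene-label permutations, sign-matched normalisation (NES), and
Benjamini-Hochberg control within each sign class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from ._stats import bh_adjust
from .io import GeneSetCollection, OmicsMatrix

logger = logging.getLogger(__name__)

DEFAULT_Q_CUT = 0.01
DEFAULT_FC_CUT = float(np.log2(1.5))


def min_psm_per_protein(psm: pd.DataFrame, contributing_sets: list[str]) -> pd.Series:
    """Minimum per-TMT-set summed PSM count over the contributing sets.

    Zero and missing counts are ignored; genes with no quantified PSM in any
    contributing set are excluded from the result.
    """
    if not contributing_sets:
        raise ValueError("contributing_sets must be non-empty")
    sub = psm[list(contributing_sets)].to_numpy(dtype=float)
    sub = np.where(np.isfinite(sub) & (sub > 0), sub, np.nan)
    any_ok = np.isfinite(sub).any(axis=1)
    mins = np.full(sub.shape[0], np.nan)
    if any_ok.any():
        mins[any_ok] = np.nanmin(sub[any_ok], axis=1)
    out = pd.Series(mins, index=psm.index, name="min_psm")
    return out.dropna()


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-8 * x:
            break
    return float(x)


@dataclass
class ModeratedTestResult:
    table: pd.DataFrame        # per-gene statistics
    prior_df: float
    n_dropped: int


def moderated_ttest(matrix: OmicsMatrix, group_a: list[str], group_b: list[str],
                    other: list[str] | None = None,
                    min_psm: pd.Series | None = None,
                    q_cut: float = DEFAULT_Q_CUT,
                    fc_cut: float = DEFAULT_FC_CUT,
                    trend: str = "lowess",
                    prior_df: float | str = "auto",
                    lowess_frac: float = 0.5) -> ModeratedTestResult:
    """Two-group contrast with PSM-trended empirical-Bayes variance moderation.

    ``group_a`` / ``group_b`` are sample lists; remaining samples can be
    passed as a pooled ``other`` stratum that contributes to the variance
    estimate only.  Genes must have at least one valid value per stratum.
    ``prior_df='auto'`` estimates the prior degrees of freedom from the data;
    ``trend='none'`` with ``prior_df=0`` reduces to the ordinary pooled
    two-sample t-test.  When ``min_psm`` is given only covered genes are
    tested and the variance trend is fitted on log min PSM; otherwise the
    trend is a constant.
    """
    strata = [list(group_a), list(group_b)] + ([list(other)] if other else [])
    flat = [s for grp in strata for s in grp]
    if len(set(flat)) != len(flat):
        raise ValueError("groups overlap")
    vals = matrix.values
    genes = list(vals.index)
    if min_psm is not None:
        genes = [g for g in genes if g in min_psm.index]
    sub = vals.loc[genes]

    blocks = [sub[grp].to_numpy(dtype=float) for grp in strata]
    ns = [np.isfinite(b).sum(axis=1) for b in blocks]
    valid = np.all([n >= 1 for n in ns], axis=0)
    df_resid = sum(ns) - len(strata)
    valid &= df_resid >= 1

    import warnings as _warnings
    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        means = [np.nanmean(b, axis=1) for b in blocks]
        ss = [np.nansum((b - m[:, None]) ** 2, axis=1) for b, m in zip(blocks, means)]
    s2 = np.where(valid, sum(ss) / np.where(df_resid > 0, df_resid, 1), np.nan)
    s2 = np.maximum(s2, 1e-300)
    log_fc = means[0] - means[1]

    keep = valid & np.isfinite(log_fc)
    n_dropped = int((~keep).sum())
    idx = np.flatnonzero(keep)
    genes_kept = [genes[i] for i in idx]
    s2k = s2[idx]
    d1 = df_resid[idx].astype(float)
    n_a, n_b = ns[0][idx].astype(float), ns[1][idx].astype(float)
    fc = log_fc[idx]

    z = np.log(s2k)
    if trend == "lowess" and min_psm is not None:
        x = np.log(min_psm.loc[genes_kept].to_numpy(dtype=float))
        order = np.argsort(x)
        sm = lowess(z[order], x[order], frac=lowess_frac, it=0, return_sorted=False)
        trend_z = np.empty_like(z)
        trend_z[order] = sm
    elif trend in ("lowess", "none"):
        trend_z = np.full_like(z, z.mean())
    else:
        raise ValueError(f"unknown trend {trend!r}")

    # method-of-moments on log s^2 around the trend: residual variance in
    # excess of trigamma(d1/2) reflects true variance spread -> prior df d0
    e = z - trend_z
    mean_tri = float(np.mean(special.polygamma(1, d1 / 2.0)))
    if prior_df == "auto":
        evar = float(np.var(e, ddof=1)) - mean_tri
        d0 = 2.0 * _trigamma_inverse(evar) if evar > 1e-10 else np.inf
    else:
        d0 = float(prior_df)

    # centre the trend so exp(.) estimates the prior variance s0^2
    bias = special.digamma(d1 / 2.0) - np.log(d1 / 2.0)
    if np.isfinite(d0) and d0 > 0:
        bias = bias - special.digamma(d0 / 2.0) + np.log(d0 / 2.0)
    s0_sq = np.exp(trend_z - bias + (float(np.mean(e)) if prior_df == "auto" else 0.0))

    if d0 == 0:
        post_var = s2k
        df_total = d1
    elif np.isinf(d0):
        post_var = s0_sq
        df_total = np.full_like(d1, np.inf)
    else:
        post_var = (d0 * s0_sq + d1 * s2k) / (d0 + d1)
        df_total = d1 + d0

    se = np.sqrt(post_var * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = fc / se
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    q = bh_adjust(p)
    sig = (q <= q_cut) & (np.abs(fc) >= fc_cut)

    table = pd.DataFrame({
        "log2_fc": fc, "mean_a": means[0][idx], "mean_b": means[1][idx],
        "pooled_var": s2k, "moderated_var": post_var,
        "t": t, "df": df_total, "p": p, "q": q,
        "min_psm": (min_psm.loc[genes_kept].to_numpy(dtype=float)
                    if min_psm is not None else np.nan),
        "significant": sig,
    }, index=pd.Index(genes_kept, name="gene"))
    logger.info("moderated test: %d genes, %d dropped, prior df %.2f, %d significant",
                len(table), n_dropped, d0 if np.isfinite(d0) else np.inf,
                int(sig.sum()))
    return ModeratedTestResult(table=table, prior_df=float(d0), n_dropped=n_dropped)


def mrna_welch_contrast(matrix: OmicsMatrix, group_a: list[str],
                        group_b: list[str]) -> pd.DataFrame:
    """Welch t contrast on log2(TPM) values — a simple stand-in for count-based
    RNA differential expression, labelled as such."""
    a = matrix.values[list(group_a)].to_numpy(dtype=float)
    b = matrix.values[list(group_b)].to_numpy(dtype=float)
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=False, nan_policy="omit")
    fc = np.nanmean(a, axis=1) - np.nanmean(b, axis=1)
    return pd.DataFrame({"log2_fc": fc, "t": t, "p": p, "q": bh_adjust(p)},
                        index=matrix.values.index)


# ---------------------------------------------------------------------------
# preranked GSEA
# ---------------------------------------------------------------------------

def enrichment_score(scores: np.ndarray, hit_mask: np.ndarray,
                     weight: float = 1.0) -> tuple[float, int]:
    """Weighted KS enrichment score for one set on a ranked score vector.

    Hits advance the running sum by |score|^weight (normalised over hits),
    misses retreat by 1/(N - n_hits).  Returns (ES, peak_index) where ES is
    the running-sum value of largest magnitude.
    """
    scores = np.asarray(scores, dtype=float)
    hit_mask = np.asarray(hit_mask, dtype=bool)
    n = scores.size
    nh = int(hit_mask.sum())
    if nh == 0 or nh == n:
        raise ValueError("set must hit a strict subset of the ranking")
    w = np.abs(scores) ** weight
    hit_sum = w[hit_mask].sum()
    if hit_sum == 0:
        w = np.ones_like(w)
        hit_sum = float(nh)
    steps = np.where(hit_mask, w / hit_sum, -1.0 / (n - nh))
    running = np.cumsum(steps)
    peak = int(np.argmax(np.abs(running)))
    return float(running[peak]), peak


def _permutation_es(scores: np.ndarray, nh: int, weight: float,
                    n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """ES of ``n_perm`` random sets of size nh (gene-label permutation null)."""
    n = scores.size
    w = np.abs(scores) ** weight
    pos = np.argsort(rng.random((n_perm, n)), axis=1)[:, :nh]
    hits = np.zeros((n_perm, n), dtype=bool)
    np.put_along_axis(hits, pos, True, axis=1)
    hit_sums = np.where(hits, w[None, :], 0.0).sum(axis=1)
    hit_sums[hit_sums == 0] = nh
    steps = np.where(hits, w[None, :] / hit_sums[:, None], -1.0 / (n - nh))
    running = np.cumsum(steps, axis=1)
    peaks = np.argmax(np.abs(running), axis=1)
    return running[np.arange(n_perm), peaks]


def preranked_gsea(ranking: pd.Series, sets: GeneSetCollection,
                   weight: float = 1.0, min_size: int = 15, max_size: int = 500,
                   n_perm: int = 1000, seed: int | None = None) -> pd.DataFrame:
    """Preranked weighted-KS GSEA over a gene-score ranking.

    ``ranking`` maps unique gene ids to scores; it is sorted descending
    (ties broken by gene id) before the walk.  Permutation p-values come from
    sign-matched gene-label permutations, NES is ES over the mean magnitude
    of same-sign permutation scores, and q is BH-adjusted within sign class.
    """
    if ranking.index.has_duplicates:
        raise ValueError("ranking ids must be unique")
    ranking = ranking.sort_index().sort_values(ascending=False, kind="stable")
    ids = np.array(ranking.index)
    scores = ranking.to_numpy(dtype=float)
    id_pos = {g: i for i, g in enumerate(ids)}
    universe = set(ids)

    eligible = {}
    for name, members in sets.sets.items():
        inside = members & universe
        if min_size <= len(inside) <= max_size:
            eligible[name] = inside
    if not eligible:
        raise ValueError("no gene set within the size window overlaps the ranking")

    rng = np.random.default_rng(seed)
    perm_cache: dict[int, np.ndarray] = {}
    rows, leading = [], {}
    for name in sorted(eligible):
        inside = eligible[name]
        mask = np.zeros(ids.size, dtype=bool)
        mask[[id_pos[g] for g in inside]] = True
        es, peak = enrichment_score(scores, mask, weight=weight)
        nh = int(mask.sum())
        if nh not in perm_cache:
            perm_cache[nh] = _permutation_es(scores, nh, weight, n_perm, rng)
        perm = perm_cache[nh]
        same_sign = perm[perm >= 0] if es >= 0 else perm[perm < 0]
        if same_sign.size == 0:
            p, nes = 1.0, np.nan
        else:
            p = (1.0 + float((np.abs(same_sign) >= abs(es)).sum())) / (1.0 + same_sign.size)
            nes = es / float(np.mean(np.abs(same_sign)))
        if es >= 0:
            le = [g for g in ids[: peak + 1] if g in inside]
        else:
            le = [g for g in ids[peak:] if g in inside]
        leading[name] = le
        rows.append((name, nh, es, nes, p))

    out = pd.DataFrame(rows, columns=["set", "size", "es", "nes", "p"]).set_index("set")
    out["q"] = np.nan
    for sign_mask in (out["es"] >= 0, out["es"] < 0):
        if sign_mask.any():
            out.loc[sign_mask, "q"] = bh_adjust(out.loc[sign_mask, "p"].to_numpy())
    out["leading_edge"] = [";".join(leading[name]) for name in out.index]
    return out
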