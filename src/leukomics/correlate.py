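"""Gene-wise mRNA-protein correlation and complex co-regulation analysis.

Per-gene correlations between two omics layers are Spearman's rho by default
(pairwise-complete samples), with two-sided p-values from the t transform
t = r*sqrt(n-2)/sqrt(1-r^2) and Benjamini-Hochberg q-values over the table.
Co-regulation of protein-complex members is tested by comparing all
within-complex pairwise Pearson correlations to an equally sized sample of
random non-complex pairs with an unpaired two-sided t-test.  Sets of
correlations are compared on the Fisher-z scale (Welch t for two groups,
one-way ANOVA for more).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust, corr_pvalue, fisher_z, pairwise_complete_corr
from .io import ComplexCatalog, OmicsMatrix

logger = logging.getLogger(__name__)

#: complexes so large they would dominate the within-complex pair pool
DEFAULT_COMPLEX_BLOCKLIST = (
    "spliceosome",
    "nop56p-associated pre-rrna complex",
    "ribosome",
    "proteasome",
)


@dataclass
class ComplexCoregulationResult:
    within_correlations: np.ndarray
    random_correlations: np.ndarray
    mean_within: float
    mean_random: float
    t_statistic: float
    p_value: float
    excluded_complexes: list[str] = field(default_factory=list)


def paired_feature_correlation(a: OmicsMatrix, b: OmicsMatrix,
                               method: str = "spearman",
                               min_n: int = 10) -> pd.DataFrame:
    """One correlation record per feature shared by two sample-aligned layers.

    Returns a DataFrame indexed by feature with columns r, n_pairs, p, q.
    Features with fewer than ``min_n`` pairwise-complete samples are dropped
    (their count is logged).
    """
    if a.sample_ids != b.sample_ids:
        raise ValueError("matrices must be sample-aligned (see align_samples)")
    shared = [f for f in a.feature_ids if f in set(b.feature_ids)]
    if not shared:
        raise ValueError("no shared features between layers")
    av = a.values.loc[shared].to_numpy(dtype=float)
    bv = b.values.loc[shared].to_numpy(dtype=float)
    rs, ns = [], []
    for x, y in zip(av, bv):
        r, n = pairwise_complete_corr(x, y, method=method, min_n=min_n)
        rs.append(r)
        ns.append(n)
    df = pd.DataFrame({"r": rs, "n_pairs": ns}, index=pd.Index(shared, name="gene"))
    dropped = int((df["n_pairs"] < min_n).sum() + df["r"].isna().sum())
    df = df[(df["n_pairs"] >= min_n) & df["r"].notna()]
    df["p"] = corr_pvalue(df["r"].to_numpy(), df["n_pairs"].to_numpy())
    df["q"] = bh_adjust(df["p"].to_numpy())
    logger.info("paired correlation (%s): %d features kept, %d dropped, median r %.3f",
                method, len(df), dropped, df["r"].median())
    return df


def complex_coregulation_test(matrix: OmicsMatrix, catalog: ComplexCatalog,
                              n_random: int | None = None,
                              blocklist: tuple[str, ...] = DEFAULT_COMPLEX_BLOCKLIST,
                              min_n: int = 10,
                              seed: int | None = None) -> ComplexCoregulationResult:
    """Within-complex vs. random-pair correlation test on one omics layer.

    All pairwise Pearson correlations between quantified members of each
    non-blocklisted complex are pooled and compared to ``n_random`` uniformly
    sampled non-complex pairs (default: as many as there are within-complex
    pairs) via an unpaired two-sided t-test.
    """
    rng = np.random.default_rng(seed)
    features = {g: i for i, g in enumerate(matrix.feature_ids)}
    vals = matrix.values.to_numpy(dtype=float)

    excluded = [cid for cid in catalog.complexes
                if catalog.names.get(cid, "").strip().lower() in blocklist]
    within_pairs: set[tuple[int, int]] = set()
    for cid, members in catalog.complexes.items():
        if cid in excluded:
            continue
        idx = sorted(features[g] for g in members if g in features)
        for i in range(len(idx)):
            for j in range(i + 1, len(idx)):
                within_pairs.add((idx[i], idx[j]))
    if not within_pairs:
        raise ValueError("no complex with >= 2 quantified members")

    def pair_corrs(pairs):
        out = []
        for i, j in pairs:
            r, n = pairwise_complete_corr(vals[i], vals[j], method="pearson",
                                          min_n=min_n)
            if np.isfinite(r):
                out.append(r)
        return np.asarray(out)

    within_r = pair_corrs(sorted(within_pairs))
    if within_r.size == 0:
        raise ValueError("no within-complex pair passed the min_n filter")

    n_random = len(within_pairs) if n_random is None else n_random
    nf = len(features)
    random_pairs: set[tuple[int, int]] = set()
    max_avail = nf * (nf - 1) // 2 - len(within_pairs)
    n_random = min(n_random, max_avail)
    while len(random_pairs) < n_random:
        draw = rng.integers(0, nf, size=(2 * (n_random - len(random_pairs)) + 8, 2))
        for i, j in draw:
            if i == j:
                continue
            pair = (min(i, j), max(i, j))
            if pair in within_pairs or pair in random_pairs:
                continue
            random_pairs.add(pair)
            if len(random_pairs) == n_random:
                break
    random_r = pair_corrs(sorted(random_pairs))

    t, p = stats.ttest_ind(within_r, random_r, equal_var=True)
    return ComplexCoregulationResult(
        within_correlations=within_r, random_correlations=random_r,
        mean_within=float(within_r.mean()), mean_random=float(random_r.mean()),
        t_statistic=float(t), p_value=float(p), excluded_complexes=excluded)


def grouped_correlation_test(correlations: pd.Series | pd.DataFrame,
                             grouping: dict[str, str],
                             mode: str | None = None) -> tuple[float, float]:
    """Compare groups of correlations on the Fisher-z scale.

    Two groups: Welch's two-sided t-test.  More: one-way ANOVA.  |r| = 1 is
    clipped just inside (-1, 1) before the atanh transform.  ``correlations``
    is a Series of r indexed by feature (or a table with an ``r`` column).
    Returns (statistic, p).
    """
    if isinstance(correlations, pd.DataFrame):
        correlations = correlations["r"]
    groups: dict[str, list[float]] = {}
    for feat, grp in grouping.items():
        if feat in correlations.index:
            groups.setdefault(grp, []).append(correlations.loc[feat])
    groups = {g: v for g, v in groups.items() if len(v) >= 3}
    if len(groups) < 2:
        raise ValueError("need >= 2 groups with >= 3 members each")
    zs = [fisher_z(np.asarray(v)) for v in groups.values()]
    n_groups = len(zs)
    if mode is None:
        mode = "two_group" if n_groups == 2 else "multi_group"
    if mode == "two_group":
        if n_groups != 2:
            raise ValueError("two_group mode requires exactly 2 groups")
        stat, p = stats.ttest_ind(zs[0], zs[1], equal_var=False)
    elif mode == "multi_group":
        stat, p = stats.f_oneway(*zs)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(stat), float(p)


def rank_genes(correlations: pd.DataFrame) -> pd.Series:
    """Features ordered by descending r, ties broken lexicographically.

    The returned Series (index = feature, values = r) feeds preranked GSEA
    without further transformation.
    """
    if correlations.empty:
        raise ValueError("empty correlation table")
    df = correlations.sort_index().sort_values("r", ascending=False, kind="stable")
    return df["r"]
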