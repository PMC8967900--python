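"""Subsampled consensus clustering with CDF delta-area selection of k.

Each resampling round draws a fraction of samples and features, clusters the
subsample hierarchically with a 1 - correlation distance, and cuts the tree
at k.  The consensus matrix entry (i, j) is the fraction of rounds in which
the two samples co-clustered among rounds where both were drawn.  The number
of clusters is picked from the relative growth in the area under the
consensus CDF (the delta-area elbow), with manual override first-class.
Samples uncorrelated with every other sample (max pairwise Pearson below a
floor) are flagged beforehand and excluded from the consensus runs; the
final assignment reinstates them, and replicate samples inherit their
parent's cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform

from .io import OmicsMatrix, SampleMetadata

logger = logging.getLogger(__name__)

_LINKAGE_MAP = {"ward": "ward", "average": "average", "complete": "complete"}


@dataclass
class ConsensusResult:
    k_range: list[int]
    consensus: dict[int, pd.DataFrame]   # k -> samples x samples matrix
    areas: dict[int, float]              # k -> area under consensus CDF
    delta_areas: dict[int, float]        # k -> relative delta area
    chosen_k: int
    sample_ids: list[str]


@dataclass
class ClusterAssignment:
    assignments: pd.Series               # sample -> cluster label (1..k)
    bootstrap_support: dict[int, float] = field(default_factory=dict)


def _sample_correlation(values: np.ndarray, method: str = "pearson") -> np.ndarray:
    """Correlation between columns (samples); pairwise-complete under NaN."""
    if method == "spearman":
        df = pd.DataFrame(values)
        values = df.rank(axis=0, na_option="keep").to_numpy()
    if np.isfinite(values).all():
        return np.corrcoef(values, rowvar=False)
    return pd.DataFrame(values).corr(method="pearson").to_numpy()


def _hierarchical_cut(values: np.ndarray, k: int, distance: str,
                      linkage: str) -> np.ndarray:
    """Cluster columns of a features x samples block; labels 1..k."""
    corr = _sample_correlation(values, method=distance)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    d = np.nan_to_num(d, nan=2.0)  # never-overlapping pairs: maximal distance
    z = scipy_linkage(squareform(d, checks=False), method=_LINKAGE_MAP[linkage])
    return fcluster(z, t=k, criterion="maxclust")


def flag_outlier_samples(matrix: OmicsMatrix, r_min: float = 0.5) -> pd.Series:
    """Flag samples with no Pearson correlation >= r_min to any other sample,
    computed on pairwise-complete (valid) values."""
    if len(matrix.sample_ids) < 2:
        raise ValueError("need >= 2 samples")
    corr = _sample_correlation(matrix.values.to_numpy(dtype=float))
    np.fill_diagonal(corr, -np.inf)
    best = np.nanmax(corr, axis=1)
    flags = pd.Series(best < r_min, index=matrix.sample_ids, name="outlier")
    if flags.any():
        logger.info("outlier samples: %s", list(flags.index[flags]))
    return flags


def consensus_cluster(matrix: OmicsMatrix, features: list[str] | None = None,
                      k_range: range | list[int] = range(2, 9),
                      reps: int = 2000, p_item: float = 0.8,
                      p_feature: float = 0.8, distance: str = "pearson",
                      linkage: str = "ward", seed: int | None = None,
                      delta_frac: float = 0.1,
                      exclude_samples: list[str] | None = None) -> ConsensusResult:
    """Consensus clustering over a k range with automatic elbow selection.

    ``chosen_k`` is the largest k whose relative delta area (the area under
    the consensus CDF for the first k; the relative increase thereafter)
    exceeds ``delta_frac``; the full delta-area curve is returned so a manual
    choice can override it.
    """
    sub = matrix
    if features is not None:
        sub = matrix.subset_features(features)
    if exclude_samples:
        keep = [s for s in sub.sample_ids if s not in set(exclude_samples)]
        sub = sub.subset_samples(keep)
    k_range = sorted(k_range)
    n = len(sub.sample_ids)
    m = len(sub.feature_ids)
    if m < 10:
        raise ValueError("need >= 10 features for consensus clustering")
    if k_range[0] < 2 or k_range[-1] > n - 1:
        raise ValueError(f"k_range must lie within [2, {n - 1}]")

    rng = np.random.default_rng(seed)
    vals = sub.values.to_numpy(dtype=float)
    n_item = int(np.ceil(p_item * n))
    n_feat = int(np.ceil(p_feature * m))

    co_sampled = np.zeros((n, n))
    co_clustered = {k: np.zeros((n, n)) for k in k_range}
    for _ in range(reps):
        items = np.sort(rng.choice(n, size=n_item, replace=False))
        feats = rng.choice(m, size=n_feat, replace=False)
        block = vals[np.ix_(feats, items)]
        pair_mask = np.zeros((n, n))
        pair_mask[np.ix_(items, items)] = 1.0
        co_sampled += pair_mask
        for k in k_range:
            labels = _hierarchical_cut(block, k, distance, linkage)
            same = labels[:, None] == labels[None, :]
            co_clustered[k][np.ix_(items, items)] += same
    consensus = {}
    with np.errstate(invalid="ignore"):
        for k in k_range:
            c = np.where(co_sampled > 0, co_clustered[k] / co_sampled, 0.0)
            np.fill_diagonal(c, 1.0)
            consensus[k] = pd.DataFrame(c, index=sub.sample_ids,
                                        columns=sub.sample_ids)

    areas = {k: _cdf_area(consensus[k].to_numpy()) for k in k_range}
    delta = {}
    prev = None
    for k in k_range:
        if prev is None:
            delta[k] = areas[k]
        else:
            delta[k] = (areas[k] - areas[prev]) / areas[prev] if areas[prev] > 0 else 0.0
        prev = k
    qualifying = [k for k in k_range if delta[k] > delta_frac]
    chosen = max(qualifying) if qualifying else k_range[0]
    logger.info("consensus areas %s; delta %s; chosen k=%d",
                {k: round(a, 3) for k, a in areas.items()},
                {k: round(d, 3) for k, d in delta.items()}, chosen)
    return ConsensusResult(k_range=list(k_range), consensus=consensus,
                           areas=areas, delta_areas=delta, chosen_k=chosen,
                           sample_ids=sub.sample_ids)


def _cdf_area(consensus: np.ndarray, n_bins: int = 100) -> float:
    """Area under the empirical CDF of upper-triangle consensus entries."""
    iu = np.triu_indices(consensus.shape[0], k=1)
    vals = consensus[iu]
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    cdf = np.searchsorted(np.sort(vals), edges[1:], side="right") / vals.size
    widths = np.diff(edges)
    return float(np.sum(widths * cdf))


def finalize_clusters(matrix: OmicsMatrix, chosen_k: int,
                      metadata: SampleMetadata | None = None,
                      distance: str = "pearson", linkage: str = "ward",
                      n_bootstrap: int = 500,
                      seed: int | None = None) -> ClusterAssignment:
    """Final hierarchical clustering on all features and samples.

    Replicate samples are held out of the tree and assigned the cluster of
    their parents.  Per-cluster support is the fraction of feature-bootstrap
    replicates in which the cluster's exact member set recurs (a plain
    bootstrap recurrence measure, simpler than multiscale bootstrap).
    """
    rng = np.random.default_rng(seed)
    replicate_of: dict[str, str] = {}
    if metadata is not None:
        for s, p in metadata.table["replicate_of"].items():
            if pd.notna(p) and s in matrix.sample_ids:
                replicate_of[s] = p
    core = [s for s in matrix.sample_ids if s not in replicate_of]
    vals = matrix.values[core].to_numpy(dtype=float)
    if chosen_k > len(core):
        raise ValueError("chosen_k exceeds the number of non-replicate samples")
    labels = _hierarchical_cut(vals, chosen_k, distance, linkage)
    assign = {s: int(l) for s, l in zip(core, labels)}
    for s, p in replicate_of.items():
        assign[s] = assign[p]
    assignments = pd.Series(assign, name="cluster")

    clusters = {lab: frozenset(s for s in core if assign[s] == lab)
                for lab in sorted(set(labels))}
    hits = {lab: 0 for lab in clusters}
    m = vals.shape[0]
    for _ in range(n_bootstrap):
        feats = rng.integers(0, m, size=m)
        boot_labels = _hierarchical_cut(vals[feats], chosen_k, distance, linkage)
        boot_sets = {frozenset(np.array(core)[boot_labels == lab])
                     for lab in set(boot_labels)}
        for lab, members in clusters.items():
            if members in boot_sets:
                hits[lab] += 1
    support = {lab: hits[lab] / n_bootstrap for lab in clusters} \
        if n_bootstrap > 0 else {}
    return ClusterAssignment(assignments=assignments, bootstrap_support=support)
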