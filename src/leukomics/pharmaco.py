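"""Drug-response correlation layer.

Connects sDSS drug-sensitivity profiles to the omics layers: effective-drug
filtering, drug-protein and drug-drug Pearson correlation (pairwise-complete
with a minimum-n floor), ranking of each drug's putative targets among all
feature correlations, a PCA + UMAP embedding of drug correlation profiles,
a paired protein-vs-mRNA correlation-strength comparison on the Fisher-z
scale, and lineage differential correlation with the standard z-difference
statistic plus a group-label permutation p.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import (bh_adjust, columnwise_corr_with_vector, corr_pvalue,
                     fisher_z, fisher_z_difference)
from .io import DrugAnnotation, DrugResponseMatrix, OmicsMatrix

logger = logging.getLogger(__name__)


@dataclass
class DrugProteinCorrResult:
    r: pd.DataFrame          # drugs x features Pearson r
    n: pd.DataFrame          # pairwise-complete sample counts
    p: pd.DataFrame          # two-sided t-transform p-values
    target_ranks: pd.DataFrame | None = None   # per (drug, target) rank records
    top_features: dict[str, list[str]] = field(default_factory=dict)


def filter_effective_drugs(sdss: DrugResponseMatrix, threshold: float = 8.0,
                           min_lines: int = 2) -> list[str]:
    """Drugs reaching sDSS >= threshold in at least ``min_lines`` cell lines
    (missing values never qualify)."""
    if min_lines < 1:
        raise ValueError("min_lines must be >= 1")
    vals = sdss.sdss.to_numpy(dtype=float)
    counts = np.nansum(np.where(np.isfinite(vals), vals >= threshold, False), axis=1)
    retained = [d for d, c in zip(sdss.drug_ids, counts) if c >= min_lines]
    logger.info("effective drugs: %d of %d retained (sDSS >= %g in >= %d lines)",
                len(retained), len(sdss.drug_ids), threshold, min_lines)
    return retained


def drug_feature_correlations(sdss: DrugResponseMatrix, features: OmicsMatrix,
                              min_n: int = 10,
                              annotations: DrugAnnotation | None = None,
                              top_k: int = 10) -> DrugProteinCorrResult:
    """Pearson r of each drug's sDSS profile against every feature.

    Entries with fewer than ``min_n`` complete pairs are missing and are
    excluded from ranking.  When annotations are given, each putative
    target's rank among all features (descending r, lexicographic
    tie-break) is reported.
    """
    if sdss.sample_ids != features.sample_ids:
        raise ValueError("sDSS and feature matrices must be sample-aligned")
    fv = features.values.to_numpy(dtype=float)
    feature_ids = np.array(features.feature_ids)
    r_rows, n_rows = [], []
    for drug in sdss.drug_ids:
        vec = sdss.sdss.loc[drug].to_numpy(dtype=float)
        r, n = columnwise_corr_with_vector(fv, vec, min_n=min_n)
        r_rows.append(r)
        n_rows.append(n)
    r = pd.DataFrame(r_rows, index=sdss.drug_ids, columns=feature_ids)
    n = pd.DataFrame(n_rows, index=sdss.drug_ids, columns=feature_ids)
    p = pd.DataFrame(corr_pvalue(r.to_numpy(), n.to_numpy(dtype=float)),
                     index=r.index, columns=r.columns)

    top_features: dict[str, list[str]] = {}
    rank_records = []
    for drug in r.index:
        row = r.loc[drug].dropna()
        ordered = row.sort_index().sort_values(ascending=False, kind="stable")
        top_features[drug] = list(ordered.index[:top_k])
        if annotations is not None and drug in annotations.table.index:
            ranks = pd.Series(np.arange(1, len(ordered) + 1), index=ordered.index)
            for target in annotations.targets_of(drug):
                if target in ranks.index:
                    rank_records.append((drug, target, int(ranks[target]),
                                         float(ordered[target]), len(ordered)))
    target_ranks = (pd.DataFrame(rank_records,
                                 columns=["drug", "target", "rank", "r",
                                          "n_features"])
                    if annotations is not None else None)
    return DrugProteinCorrResult(r=r, n=n, p=p, target_ranks=target_ranks,
                                 top_features=top_features)


def drug_drug_correlations(sdss: DrugResponseMatrix, min_n: int = 10) -> pd.DataFrame:
    """All-pairs Pearson correlation of sDSS profiles with t-transform p and
    BH q; pairwise-complete samples, pairs under ``min_n`` dropped."""
    drugs = sdss.drug_ids
    if len(drugs) < 2:
        raise ValueError("need >= 2 drugs")
    vals = sdss.sdss.to_numpy(dtype=float)
    rows = []
    for i in range(len(drugs)):
        for j in range(i + 1, len(drugs)):
            x, y = vals[i], vals[j]
            ok = np.isfinite(x) & np.isfinite(y)
            npairs = int(ok.sum())
            if npairs < min_n:
                continue
            if np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
                continue
            r = float(stats.pearsonr(x[ok], y[ok]).statistic)
            rows.append((drugs[i], drugs[j], r, npairs))
    df = pd.DataFrame(rows, columns=["drug_a", "drug_b", "r", "n_pairs"])
    df["p"] = corr_pvalue(df["r"].to_numpy(), df["n_pairs"].to_numpy())
    df["q"] = bh_adjust(df["p"].to_numpy())
    return df


@dataclass
class PairedCorrComparison:
    mean_z_difference: float   # protein minus mRNA, Fisher-z of |r|
    statistic: float
    p_value: float
    n_pairs: int
    test: str


def compare_protein_vs_rna_correlation(sdss: DrugResponseMatrix,
                                       protein: OmicsMatrix, mrna: OmicsMatrix,
                                       min_n: int = 10,
                                       test: str = "paired_t") -> PairedCorrComparison:
    """Paired comparison of |drug-protein| vs |drug-mRNA| correlation strength.

    For each (drug, gene) quantified in both layers the absolute Pearson
    correlations are mapped to Fisher z and compared with a paired two-sided
    t-test (Wilcoxon signed-rank optional).  A positive mean difference means
    protein levels track drug response more closely than mRNA levels.
    """
    from .io import align_samples

    prot_a, sdss_a, _ = align_samples(protein, sdss)
    mrna_a, sdss_b, _ = align_samples(mrna, sdss)
    shared_genes = sorted(set(prot_a.feature_ids) & set(mrna_a.feature_ids))
    if not shared_genes:
        raise ValueError("no genes shared between the two layers")
    res_p = drug_feature_correlations(sdss_a, prot_a.subset_features(shared_genes),
                                      min_n=min_n)
    res_m = drug_feature_correlations(sdss_b, mrna_a.subset_features(shared_genes),
                                      min_n=min_n)
    zp = fisher_z(np.abs(res_p.r.to_numpy()))
    zm = fisher_z(np.abs(res_m.r.to_numpy()))
    ok = np.isfinite(zp) & np.isfinite(zm)
    if not ok.any():
        raise ValueError("no (drug, gene) pair present in both layers")
    diff = zp[ok] - zm[ok]
    if test == "paired_t":
        stat, p = stats.ttest_1samp(diff, 0.0)
    elif test == "wilcoxon":
        stat, p = stats.wilcoxon(diff)
    else:
        raise ValueError(f"unknown test {test!r}")
    if np.allclose(diff, 0.0):
        stat, p = 0.0, 1.0
    return PairedCorrComparison(mean_z_difference=float(diff.mean()),
                                statistic=float(stat), p_value=float(p),
                                n_pairs=int(ok.sum()), test=test)


@dataclass
class EmbeddingResult:
    coordinates: pd.DataFrame  # drug -> (dim1, dim2)
    n_pcs: int
    n_imputed: int
    params: dict


def embed_drug_profiles(corr: pd.DataFrame, n_pcs: int = 27,
                        n_neighbors: int = 25, min_dist: float = 0.05,
                        spread: float = 3.5, local_connectivity: float = 1.0,
                        seed: int = 0) -> EmbeddingResult:
    """PCA + UMAP embedding of drug-by-feature correlation profiles.

    ``corr`` is drugs x features Pearson r; missing entries (drug/feature
    pairs below the pairwise-n floor) are imputed to 0 with the count logged.
    Features are centred and scaled, PCA reduces to min(n_pcs, rank), and
    UMAP embeds the PC scores in 2-D with a fixed seed.
    """
    from sklearn.decomposition import PCA
    from sklearn.preprocessing import StandardScaler
    import umap

    x = corr.to_numpy(dtype=float)
    n_imputed = int((~np.isfinite(x)).sum())
    x = np.nan_to_num(x, nan=0.0)
    x = StandardScaler().fit_transform(x)
    max_pcs = min(x.shape[0] - 1, x.shape[1])
    if n_pcs > max_pcs:
        logger.warning("n_pcs clamped from %d to %d", n_pcs, max_pcs)
        n_pcs = max_pcs
    scores = PCA(n_components=n_pcs, random_state=seed).fit_transform(x)
    nn = min(n_neighbors, x.shape[0] - 1)
    if nn != n_neighbors:
        logger.warning("n_neighbors clamped from %d to %d", n_neighbors, nn)
    reducer = umap.UMAP(n_neighbors=nn, min_dist=min_dist, spread=spread,
                        local_connectivity=local_connectivity,
                        n_components=2, random_state=seed)
    emb = reducer.fit_transform(scores)
    coords = pd.DataFrame(emb, index=corr.index, columns=["dim1", "dim2"])
    return EmbeddingResult(coordinates=coords, n_pcs=n_pcs, n_imputed=n_imputed,
                           params={"n_neighbors": nn, "min_dist": min_dist,
                                   "spread": spread,
                                   "local_connectivity": local_connectivity,
                                   "seed": seed})


def _group_corr(fv: np.ndarray, dv: np.ndarray, exclude_zero: bool) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature Pearson r with a drug vector; NA (and optionally zero)
    values excluded pairwise."""
    f = fv.copy()
    d = dv.copy()
    if exclude_zero:
        f = np.where(f == 0, np.nan, f)
        d = np.where(d == 0, np.nan, d)
    return columnwise_corr_with_vector(f, d, min_n=4)


def differential_correlation(sdss: DrugResponseMatrix, features: OmicsMatrix,
                             grouping: dict[str, str], n_perm: int = 1000,
                             alpha: float = 0.05, seed: int | None = None,
                             min_group_n: int = 10,
                             exclude_zero: bool = True,
                             drugs: list[str] | None = None) -> pd.DataFrame:
    """Differential drug-feature correlation between two sample groups.

    For each (drug, feature): Pearson r within each group (missing and —
    following the differential-correlation convention — zero values
    excluded), the Fisher z-difference statistic with its analytic normal p,
    a permutation p from ``n_perm`` group-label shuffles, and a sign/
    significance class label "sA/sB" with s in {+, 0, -} at per-group
    analytic correlation p < alpha.  Rows are ranked by |z-difference|.
    """
    if sdss.sample_ids != features.sample_ids:
        raise ValueError("matrices must be sample-aligned")
    labels = np.array([grouping.get(s) for s in sdss.sample_ids], dtype=object)
    names = sorted({l for l in labels if l is not None})
    if len(names) != 2:
        raise ValueError(f"grouping must define exactly 2 groups, got {names}")
    mask_a, mask_b = labels == names[0], labels == names[1]
    if mask_a.sum() < min_group_n or mask_b.sum() < min_group_n:
        raise ValueError(f"each group needs >= {min_group_n} samples")

    fv = features.values.to_numpy(dtype=float)
    feature_ids = np.array(features.feature_ids)
    rng = np.random.default_rng(seed)
    drug_list = drugs if drugs is not None else sdss.drug_ids
    pool = np.flatnonzero(mask_a | mask_b)
    n_a_samples = int(mask_a.sum())

    frames = []
    for drug in drug_list:
        dv = sdss.sdss.loc[drug].to_numpy(dtype=float)
        r_a, n_a = _group_corr(fv[:, mask_a], dv[mask_a], exclude_zero)
        r_b, n_b = _group_corr(fv[:, mask_b], dv[mask_b], exclude_zero)
        zdiff = fisher_z_difference(r_a, n_a, r_b, n_b)
        p_analytic = 2.0 * stats.norm.sf(np.abs(zdiff))

        # permutation null: reshuffle group labels within the pooled samples
        perm_count = np.zeros(fv.shape[0])
        perm_valid = np.isfinite(zdiff)
        for _ in range(n_perm):
            perm = rng.permutation(pool)
            pa, pb = perm[:n_a_samples], perm[n_a_samples:]
            pr_a, pn_a = _group_corr(fv[:, pa], dv[pa], exclude_zero)
            pr_b, pn_b = _group_corr(fv[:, pb], dv[pb], exclude_zero)
            pz = fisher_z_difference(pr_a, pn_a, pr_b, pn_b)
            perm_count += np.where(np.isfinite(pz) & perm_valid,
                                   np.abs(pz) >= np.abs(zdiff), 0.0)
        p_perm = np.where(perm_valid, (1.0 + perm_count) / (1.0 + n_perm), np.nan)

        pa_sig = corr_pvalue(r_a, n_a.astype(float)) < alpha
        pb_sig = corr_pvalue(r_b, n_b.astype(float)) < alpha
        cls_a = np.where(pa_sig, np.where(r_a > 0, "+", "-"), "0")
        cls_b = np.where(pb_sig, np.where(r_b > 0, "+", "-"), "0")
        frames.append(pd.DataFrame({
            "drug": drug, "feature": feature_ids,
            "r_a": r_a, "n_a": n_a, "r_b": r_b, "n_b": n_b,
            "z_a": fisher_z(r_a), "z_b": fisher_z(r_b),
            "z_difference": zdiff, "p_analytic": p_analytic,
            "p_permutation": p_perm,
            "class": np.char.add(np.char.add(cls_a.astype(str), "/"),
                                 cls_b.astype(str)),
        }))
    out = pd.concat(frames, ignore_index=True)
    out = out[np.isfinite(out["z_difference"])]
    out = out.reindex(out["z_difference"].abs()
                      .sort_values(ascending=False).index).reset_index(drop=True)
    out.attrs["groups"] = {"A": names[0], "B": names[1]}
    return out
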