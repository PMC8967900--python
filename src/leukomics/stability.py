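"""Protein stability scores: loess residuals of protein on mRNA.

A three-step procedure identifies per-sample protein-mRNA decoupling:

1. replicates are averaged onto their parent cell line and genes are kept
   when median TPM exceeds 1 and the protein is quantified in at least half
   of the samples;
2. for each gene, protein log2 ratio is regressed on mRNA log2 TPM across
   samples with a loess smooth, absorbing lineage-driven transcript
   differences, and residuals are standardised by the gene's residual SD;
3. samples with |z| above a cut-off (default 3) are flagged as decoupled.

Complex-level deviation in one sample is the mean z over quantified members,
which exposes coordinated events such as the collapse of a whole complex in
a single cell line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io import ComplexCatalog, OmicsMatrix, SampleMetadata, collapse_replicates

logger = logging.getLogger(__name__)


@dataclass
class StabilityFilterReport:
    n_genes_in: int
    n_kept: int
    n_dropped_tpm: int
    n_dropped_missing: int


def stability_filter(protein: OmicsMatrix, mrna: OmicsMatrix,
                     metadata: SampleMetadata | None = None,
                     tpm_threshold: float = 1.0,
                     tpm_scope: str = "median",
                     max_missing_frac: float = 0.5
                     ) -> tuple[OmicsMatrix, OmicsMatrix, StabilityFilterReport]:
    """Average replicates, align samples, and apply the TPM/missingness filters.

    The mRNA layer holds log2 TPM, so "more than 1 TPM" is log2 TPM > 0;
    ``tpm_scope`` controls how the per-sample values are reduced ("median"
    across samples by default, "all" or "any" as variants).  Proteins must be
    non-missing in at least half the samples (1 - ``max_missing_frac``).
    """
    from .io import align_samples

    if metadata is not None:
        protein = collapse_replicates(protein, metadata)
        mrna = collapse_replicates(mrna, metadata)
    protein, mrna, shared = align_samples(protein, mrna)
    genes = [g for g in protein.feature_ids if g in set(mrna.feature_ids)]
    pv = protein.values.loc[genes]
    mv = mrna.values.loc[genes]

    log2_thr = np.log2(tpm_threshold)
    if tpm_scope == "median":
        tpm_ok = mv.median(axis=1) > log2_thr
    elif tpm_scope == "all":
        tpm_ok = (mv > log2_thr).all(axis=1)
    elif tpm_scope == "any":
        tpm_ok = (mv > log2_thr).any(axis=1)
    else:
        raise ValueError(f"unknown tpm_scope {tpm_scope!r}")
    miss_ok = pv.notna().mean(axis=1) >= (1.0 - max_missing_frac)
    keep = tpm_ok & miss_ok
    if not keep.any():
        raise ValueError("no gene passed the stability filters")
    report = StabilityFilterReport(
        n_genes_in=len(genes), n_kept=int(keep.sum()),
        n_dropped_tpm=int((~tpm_ok).sum()),
        n_dropped_missing=int((tpm_ok & ~miss_ok).sum()))
    logger.info("stability filter: %s", report)
    kept = list(pv.index[keep])
    return (protein.subset_features(kept), mrna.subset_features(kept), report)


def compute_stability_scores(protein: OmicsMatrix, mrna: OmicsMatrix,
                             loess_span: float = 0.75,
                             z_cut: float = 3.0,
                             min_samples: int = 8) -> pd.DataFrame:
    """Per-gene loess of protein on mRNA; standardized residuals and flags.

    Returns a long-format table with columns gene, sample, fitted, residual,
    z, significant.  Genes with degenerate mRNA values (no spread) or fewer
    than ``min_samples`` complete observations are skipped and logged.
    """
    if protein.sample_ids != mrna.sample_ids:
        raise ValueError("matrices must be sample-aligned")
    samples = np.array(protein.sample_ids)
    records = []
    skipped = 0
    for gene in protein.feature_ids:
        if gene not in mrna.values.index:
            continue
        y = protein.values.loc[gene].to_numpy(dtype=float)
        x = mrna.values.loc[gene].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < min_samples or np.ptp(x[ok]) == 0:
            skipped += 1
            continue
        xo, yo = x[ok], y[ok]
        # delta: interpolate between close x values (large speedup, same fit)
        fitted = lowess(yo, xo, frac=loess_span, it=0, return_sorted=False,
                        delta=0.01 * np.ptp(xo))
        resid = yo - fitted
        sd = resid.std(ddof=1)
        if sd <= 1e-10 * (np.abs(yo).max() + 1.0):  # numerically perfect fit
            z = np.zeros_like(resid)
        else:
            z = resid / sd
        for s, f, r, zz in zip(samples[ok], fitted, resid, z):
            records.append((gene, s, float(f), float(r), float(zz),
                            bool(abs(zz) > z_cut)))
    if skipped:
        logger.info("stability scores: %d genes skipped (insufficient/degenerate)",
                    skipped)
    return pd.DataFrame(records, columns=["gene", "sample", "fitted",
                                          "residual", "z", "significant"])


def complex_sample_deviation(table: pd.DataFrame, catalog: ComplexCatalog,
                             complex_id: str, sample: str) -> tuple[float, int]:
    """Mean standardized residual over a complex's quantified members in one
    sample; (NaN, count) with a warning when fewer than 2 members have scores."""
    members = catalog.complexes[complex_id]
    sub = table[(table["gene"].isin(members)) & (table["sample"] == sample)]
    n = len(sub)
    if n < 2:
        logger.warning("complex %s has %d scored member(s) in sample %s",
                       complex_id, n, sample)
        return np.nan, n
    return float(sub["z"].mean()), n
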