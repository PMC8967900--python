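"""Ground-truthed synthetic cohort generator.

Emulates the statistical structure of a TMT proteome / RNA-seq transcriptome /
drug-sensitivity cell-line panel:

* per-gene mRNA-protein coupling with a tunable median Spearman correlation
  (default 0.55), realised through a Gaussian-copula construction so the noise
  standard deviation is solved analytically rather than tuned;
* a bimodal protein variance structure: most genes "unmodulated" at a base
  cross-sample SD, a planted minority "highly variable" at a multiple of it,
  with variability driven by sample-group (lineage/subtype) blocks;
* protein-level co-regulation of complex members via a shared latent factor
  that is absent (by default) from the transcript layer;
* planted per-sample protein-mRNA decoupling events (additive log2 shifts on
  a few complex members in one sample);
* missing protein values (missing completely at random), per-gene PSM counts
  whose minimum-per-TMT-set decreases with per-gene variance, and drug
  responses driven by target abundance, lineage, or broad toxicity.

Everything emitted shares sample labels and is reproducible under a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (DrugResponseMatrix, OmicsMatrix, SampleMetadata,
                 MRNA_KIND, PROTEIN_KIND)


@dataclass
class SimulationConfig:
    """Knobs of the cohort generator; defaults are the study conditions."""

    n_genes: int = 3000
    n_samples: int = 64
    n_groups: int = 6
    group_lineages: Sequence[str] = ("B", "B", "B", "B", "T", "T")
    n_hv_genes: int = 300
    hv_sd_multiplier: float = 3.0
    base_protein_sd: float = 0.45
    base_mrna_sd: float = 1.0
    mrna_mean_loc: float = 4.0
    mrna_mean_scale: float = 2.0
    hv_between_group_frac: float = 0.7  # fraction of HV variance between groups
    # per-gene mRNA-protein Spearman correlation distribution
    rho_median: float = 0.55
    rho_spread: float = 0.12
    # complexes: protein-level shared latent factor
    n_complexes: int = 40
    complex_size: int = 5
    complex_latent_sd: float = 1.0  # relative to gene_noise_sd
    gene_noise_sd: float = 1.0
    transcript_latent_sd: float = 0.0
    # decoupling events: (gene, sample, shift); None -> plant default event
    decoupling_events: list | None = None
    decoupling_n_members: int = 4
    decoupling_shift: float = -2.0
    missing_rate: float = 0.05
    n_replicates: int = 3
    replicate_noise_sd: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_hv_genes > self.n_genes:
            raise ValueError("n_hv_genes cannot exceed n_genes")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if abs(self.rho_median) >= 1.0:
            raise ValueError("target median correlation must satisfy |median| < 1")
        if len(self.group_lineages) != self.n_groups:
            raise ValueError("group_lineages must have n_groups entries")


@dataclass
class DrugConfig:
    """Drug-response archetypes layered on a simulated cohort."""

    n_target_drugs: int = 20
    target_slope: float = 6.0
    target_intercept: float = 5.0
    target_noise_sd: float = 2.0
    n_lineage_drugs: int = 5
    lineage_offset: float = 10.0
    lineage_base: float = 2.0
    lineage_noise_sd: float = 2.0
    n_toxic_drugs: int = 5
    toxic_mean: float = 15.0
    toxic_sd: float = 1.5
    n_inactive_drugs: int = 10
    inactive_sd: float = 2.0
    seed: int = 0


@dataclass
class PsmConfig:
    """PSM-count generator: heavy-tailed counts anti-coupled to gene variance."""

    tmt_set_size: int = 10
    level_intercept: float = 1.2   # log count at per-gene SD = 1
    level_slope: float = 2.0       # d log(count) / d log(1/SD)
    level_jitter_sd: float = 0.3
    seed: int = 0


@dataclass
class CohortTruth:
    """Everything the generator knows that downstream analyses must recover."""

    group_of: dict[str, int]
    lineage_of: dict[str, str]
    hv_genes: list[str]
    rho_spearman: dict[str, float]       # per-gene generating Spearman target
    complex_members: dict[str, list[str]]
    decoupling_events: list[tuple[str, str, float]]
    drug_targets: dict[str, str] = field(default_factory=dict)
    drug_archetype: dict[str, str] = field(default_factory=dict)
    drug_effects: dict[str, float] = field(default_factory=dict)
    lineage_drugs: dict[str, str] = field(default_factory=dict)  # drug -> sensitive lineage

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CohortTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["decoupling_events"] = [tuple(e) for e in d["decoupling_events"]]
        return cls(**d)


def _spearman_to_pearson(rho_s: np.ndarray) -> np.ndarray:
    """Pearson correlation of a bivariate normal with given Spearman's rho."""
    return 2.0 * np.sin(np.pi * rho_s / 6.0)


def simulate_cohort(config: SimulationConfig) -> tuple[OmicsMatrix, OmicsMatrix,
                                                       SampleMetadata, CohortTruth]:
    """Generate matched protein / mRNA matrices, metadata, and ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    ng, ns = config.n_genes, config.n_samples

    genes = [f"G{i:05d}" for i in range(1, ng + 1)]
    samples = [f"CL{i:03d}" for i in range(1, ns + 1)]
    group_idx = np.sort(np.arange(ns) % config.n_groups)
    group_of = {s: int(g) for s, g in zip(samples, group_idx)}
    lineage_of = {s: config.group_lineages[g] for s, g in group_of.items()}

    hv_mask = np.zeros(ng, dtype=bool)
    hv_positions = rng.choice(ng, size=config.n_hv_genes, replace=False)
    hv_mask[hv_positions] = True

    # gene-wise Spearman targets; symmetric spread keeps the median at rho_median
    rho_s = rng.normal(config.rho_median, config.rho_spread, size=ng)
    rho_s = np.clip(rho_s, -0.5, 0.93)
    rho_p = _spearman_to_pearson(rho_s)

    # complexes tile the first n_complexes*complex_size genes
    complex_members: dict[str, list[str]] = {}
    complex_id_of = np.full(ng, -1)
    for c in range(config.n_complexes):
        members = np.arange(c * config.complex_size, (c + 1) * config.complex_size)
        members = members[members < ng]
        complex_id_of[members] = c
        complex_members[f"CPX{c + 1:03d}"] = [genes[i] for i in members]

    # shared latent z: iid noise for unmodulated genes, group-block structure
    # for HV genes, marginally N(0,1) either way
    noise = rng.standard_normal((ng, ns))
    z = noise.copy()
    vb = config.hv_between_group_frac
    group_effects = rng.standard_normal((ng, config.n_groups))
    z[hv_mask] = (np.sqrt(vb) * group_effects[hv_mask][:, group_idx]
                  + np.sqrt(1.0 - vb) * noise[hv_mask])

    mrna_mu = rng.normal(config.mrna_mean_loc, config.mrna_mean_scale, size=ng)
    sd_m = np.where(hv_mask, config.hv_sd_multiplier * config.base_mrna_sd,
                    config.base_mrna_sd)
    sd_p = np.where(hv_mask, config.hv_sd_multiplier * config.base_protein_sd,
                    config.base_protein_sd)

    # transcript layer: optional shared latent factor within complexes
    t_share = (config.transcript_latent_sd ** 2
               / (config.transcript_latent_sd ** 2 + config.gene_noise_sd ** 2)
               if config.transcript_latent_sd > 0 else 0.0)
    mrna_vals = mrna_mu[:, None] + sd_m[:, None] * z
    if t_share > 0:
        t_latent = rng.standard_normal((config.n_complexes, ns))
        in_cpx = complex_id_of >= 0
        extra = np.sqrt(t_share) * t_latent[complex_id_of[in_cpx]]
        mrna_vals[in_cpx] = (mrna_mu[in_cpx, None]
                             + sd_m[in_cpx, None] * (np.sqrt(1 - t_share) * z[in_cpx] + extra))

    # protein layer: p = sd_p * (rho*z + shared complex factor + gene noise),
    # decomposed so Var = sd_p^2 and Corr(m, p) = rho exactly
    p_share = (config.complex_latent_sd ** 2
               / (config.complex_latent_sd ** 2 + config.gene_noise_sd ** 2))
    p_latent = rng.standard_normal((max(config.n_complexes, 1), ns))
    p_noise = rng.standard_normal((ng, ns))
    resid_var = 1.0 - rho_p ** 2
    share = np.where(complex_id_of >= 0, p_share, 0.0)
    shared_part = np.sqrt(resid_var * share)[:, None] * p_latent[np.maximum(complex_id_of, 0)]
    indiv_part = np.sqrt(resid_var * (1.0 - share))[:, None] * p_noise
    protein_vals = sd_p[:, None] * (rho_p[:, None] * z + shared_part + indiv_part)

    # planted decoupling: additive protein shifts (GINS-style: a few members of
    # one complex dropping ~2 log2 units in a single sample)
    events = config.decoupling_events
    if events is None:
        cid = sorted(complex_members)[0]
        members = complex_members[cid][: config.decoupling_n_members]
        target_sample = samples[int(rng.integers(ns))]
        events = [(g, target_sample, config.decoupling_shift) for g in members]
    gene_pos = {g: i for i, g in enumerate(genes)}
    sample_pos = {s: j for j, s in enumerate(samples)}
    for g, s, shift in events:
        if not np.isfinite(shift):
            raise ValueError(f"decoupling shift for ({g}, {s}) is not finite")
        protein_vals[gene_pos[g], sample_pos[s]] += shift

    # replicate columns (protein layer only), then MCAR missingness
    rep_names, rep_parent = [], []
    rep_cols = []
    for i in range(config.n_replicates):
        parent = samples[i % ns]
        rep_names.append(f"{parent}R")
        rep_parent.append(parent)
        rep_cols.append(protein_vals[:, i % ns]
                        + rng.normal(0, config.replicate_noise_sd, size=ng))
    all_prot = np.column_stack([protein_vals] + [c[:, None] for c in rep_cols]) \
        if rep_cols else protein_vals
    prot_samples = samples + rep_names
    if config.missing_rate > 0:
        miss = rng.random(all_prot.shape) < config.missing_rate
        all_prot = np.where(miss, np.nan, all_prot)

    protein = OmicsMatrix(pd.DataFrame(all_prot, index=genes, columns=prot_samples),
                          kind=PROTEIN_KIND)
    mrna = OmicsMatrix(pd.DataFrame(mrna_vals, index=genes, columns=samples),
                       kind=MRNA_KIND)

    meta_rows = []
    for s in samples:
        meta_rows.append((s, lineage_of[s], f"subtype{group_of[s] + 1}", np.nan))
    for r, parent in zip(rep_names, rep_parent):
        meta_rows.append((r, lineage_of[parent], f"subtype{group_of[parent] + 1}", parent))
    meta = SampleMetadata(pd.DataFrame(
        [(lin, sub, rep) for _, lin, sub, rep in meta_rows],
        index=pd.Index([s for s, *_ in meta_rows], name="sample_id"),
        columns=["lineage", "subtype", "replicate_of"]))

    truth = CohortTruth(
        group_of={**group_of, **{r: group_of[p] for r, p in zip(rep_names, rep_parent)}},
        lineage_of={**lineage_of, **{r: lineage_of[p] for r, p in zip(rep_names, rep_parent)}},
        hv_genes=[genes[i] for i in np.flatnonzero(hv_mask)],
        rho_spearman={g: float(r) for g, r in zip(genes, rho_s)},
        complex_members=complex_members,
        decoupling_events=[(g, s, float(sh)) for g, s, sh in events],
    )
    return protein, mrna, meta, truth


def simulate_drug_response(protein: OmicsMatrix, truth: CohortTruth,
                           drug_config: DrugConfig | None = None,
                           samples: list[str] | None = None) -> DrugResponseMatrix:
    """Layer drug responses on a cohort: target-driven, lineage-driven, and
    broadly toxic archetypes (plus inactive drugs for the effectiveness filter).

    Target-driven drugs follow sDSS = slope * target_protein + intercept + noise
    with the target gene recorded in the truth object.
    """
    cfg = drug_config or DrugConfig()
    rng = np.random.default_rng(cfg.seed)
    if samples is None:
        samples = [s for s in protein.sample_ids if s in truth.lineage_of]
    vals = protein.values[samples]
    # mean-impute missing protein values for response construction
    filled = vals.to_numpy(dtype=float)
    row_means = np.nanmean(filled, axis=1)
    filled = np.where(np.isfinite(filled), filled, row_means[:, None])
    genes = protein.feature_ids
    ns = len(samples)
    lineages = np.array([truth.lineage_of[s] for s in samples])

    rows, drug_ids = [], []
    candidates = [i for i, g in enumerate(genes) if np.isfinite(row_means[i])]
    target_idx = rng.choice(candidates, size=cfg.n_target_drugs, replace=False)
    for k, gi in enumerate(target_idx):
        d = f"DRUG_T{k + 1:03d}"
        level = filled[gi] - filled[gi].mean()
        sdss = (cfg.target_slope * level + cfg.target_intercept
                + rng.normal(0, cfg.target_noise_sd, ns))
        rows.append(sdss)
        drug_ids.append(d)
        truth.drug_targets[d] = genes[gi]
        truth.drug_archetype[d] = "target"
        truth.drug_effects[d] = cfg.target_slope
    for k in range(cfg.n_lineage_drugs):
        d = f"DRUG_L{k + 1:03d}"
        lin = "B" if k % 2 == 0 else "T"
        sdss = (cfg.lineage_base + cfg.lineage_offset * (lineages == lin)
                + rng.normal(0, cfg.lineage_noise_sd, ns))
        rows.append(sdss)
        drug_ids.append(d)
        truth.drug_archetype[d] = "lineage"
        truth.drug_effects[d] = cfg.lineage_offset
        truth.lineage_drugs[d] = lin
    for k in range(cfg.n_toxic_drugs):
        d = f"DRUG_X{k + 1:03d}"
        rows.append(rng.normal(cfg.toxic_mean, cfg.toxic_sd, ns))
        drug_ids.append(d)
        truth.drug_archetype[d] = "toxic"
    for k in range(cfg.n_inactive_drugs):
        d = f"DRUG_N{k + 1:03d}"
        rows.append(rng.normal(0.0, cfg.inactive_sd, ns))
        drug_ids.append(d)
        truth.drug_archetype[d] = "inactive"

    return DrugResponseMatrix(pd.DataFrame(np.vstack(rows), index=drug_ids,
                                           columns=samples))


def simulate_psm_counts(protein: OmicsMatrix, config: PsmConfig | None = None
                        ) -> pd.DataFrame:
    """Per-gene, per-TMT-set summed PSM counts (genes x sets).

    Samples are partitioned into consecutive TMT sets.  Counts are drawn from
    a lognormal level anti-coupled to each gene's robust cross-sample SD (high
    variance <-> shallow PSM evidence), with per-set Poisson variation, so a
    variance-vs-min-PSM moderation trend is present by construction.
    """
    cfg = config or PsmConfig()
    rng = np.random.default_rng(cfg.seed)
    vals = protein.values.to_numpy(dtype=float)
    ng, ns = vals.shape
    n_sets = max(1, int(np.ceil(ns / cfg.tmt_set_size)))

    sd = np.array([np.nanstd(row, ddof=1) if np.isfinite(row).sum() > 1 else np.nan
                   for row in vals])
    sd = np.where(np.isfinite(sd) & (sd > 0), sd, np.nanmedian(sd))
    log_level = (cfg.level_intercept - cfg.level_slope * np.log(sd)
                 + rng.normal(0, cfg.level_jitter_sd, ng))
    level = np.exp(log_level)
    counts = rng.poisson(level[:, None], size=(ng, n_sets))
    cols = [f"set{j + 1}" for j in range(n_sets)]
    return pd.DataFrame(counts, index=protein.feature_ids, columns=cols)
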