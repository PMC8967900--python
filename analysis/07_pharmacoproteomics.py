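#!/usr/bin/env python
"""The drug-response layer: correlations, target ranking, embedding, and
lineage differential correlation.

Filters effective drugs (sDSS >= 8 in >= 2 cell lines), correlates each
drug's sDSS profile with protein abundance, ranks the putative targets,
checks that protein tracks drug response better than mRNA, embeds the drug
correlation profiles with PCA + UMAP, and screens for lineage-dependent
drug-protein correlations.
"""

import argparse
from pathlib import Path

import pandas as pd

from leukomics.io import (align_samples, collapse_replicates,
                          read_drug_annotations, read_drug_matrix, read_matrix,
                          read_metadata)
from leukomics.pharmaco import (compare_protein_vs_rna_correlation,
                                differential_correlation,
                                drug_drug_correlations,
                                drug_feature_correlations, embed_drug_profiles,
                                filter_effective_drugs)
from leukomics.simulate import CohortTruth


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--perm", type=int, default=200)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    protein = read_matrix(args.cohort / "protein_log2ratio.tsv")
    mrna = read_matrix(args.cohort / "mrna_log2tpm.tsv", kind="mrna_log2tpm")
    meta = read_metadata(args.cohort / "sample_metadata.tsv")
    sdss = read_drug_matrix(args.cohort / "sdss.tsv")
    annotations = read_drug_annotations(args.cohort / "drug_annotations.tsv")
    truth = CohortTruth.from_json(args.cohort / "truth.json")
    protein = collapse_replicates(protein, meta)

    retained = filter_effective_drugs(sdss, threshold=8, min_lines=2)
    print(f"{len(retained)} of {len(sdss.drug_ids)} drugs effective "
          f"(sDSS >= 8 in >= 2 cell lines)")
    sdss_eff = pd.DataFrame(sdss.sdss.loc[retained])
    from leukomics.io import DrugResponseMatrix
    sdss_eff = DrugResponseMatrix(sdss_eff)

    sdss_a, prot_a, shared = align_samples(sdss_eff, protein)
    corr = drug_feature_correlations(sdss_a, prot_a, annotations=annotations)
    args.out.mkdir(parents=True, exist_ok=True)
    corr.r.rename_axis("drug").to_csv(args.out / "drug_protein_r.tsv", sep="\t",
                                      na_rep="NA")
    if corr.target_ranks is not None and len(corr.target_ranks):
        corr.target_ranks.to_csv(args.out / "target_ranks.tsv", sep="\t",
                                 index=False)
        rank1 = (corr.target_ranks["rank"] == 1).mean()
        print(f"putative targets at rank 1: {rank1:.0%} of "
              f"{len(corr.target_ranks)} annotated target-driven drugs")

    dd = drug_drug_correlations(sdss_a)
    dd.to_csv(args.out / "drug_drug_correlations.tsv", sep="\t", index=False)
    shared_target = dd[(dd["drug_a"].str.startswith("DRUG_T"))
                       & (dd["drug_b"].str.startswith("DRUG_T"))]
    print(f"drug-drug correlations: {len(dd)} pairs; "
          f"max r among target-driven pairs = {shared_target['r'].max():.2f}")

    cmp_res = compare_protein_vs_rna_correlation(sdss_a, protein, mrna)
    print(f"|r| protein vs mRNA (paired Fisher-z t-test over "
          f"{cmp_res.n_pairs} drug-gene pairs): mean z-difference = "
          f"{cmp_res.mean_z_difference:+.4f}, p = {cmp_res.p_value:.3g}")
    # drugs are driven by single target proteins, so the protein advantage
    # concentrates in annotated target genes; repeat restricted to those
    target_genes = sorted({g for d in retained
                           for g in annotations.targets_of(d)
                           if g in set(protein.feature_ids)})
    if target_genes:
        cmp_t = compare_protein_vs_rna_correlation(
            sdss_a, protein.subset_features(target_genes),
            mrna.subset_features(target_genes))
        print(f"  restricted to {len(target_genes)} annotated targets: "
              f"mean z-difference = {cmp_t.mean_z_difference:+.4f}, "
              f"p = {cmp_t.p_value:.3g}")

    emb = embed_drug_profiles(corr.r, n_pcs=27, seed=args.seed)
    emb.coordinates.rename_axis("drug").to_csv(
        args.out / "drug_embedding.tsv", sep="\t")
    print(f"embedded {len(emb.coordinates)} drugs on {emb.n_pcs} PCs "
          f"({emb.n_imputed} missing correlations imputed to 0)")

    grouping = {s: truth.lineage_of[s] for s in shared}
    dc = differential_correlation(sdss_a, prot_a, grouping, n_perm=args.perm,
                                  seed=args.seed,
                                  drugs=[d for d in retained
                                         if truth.drug_archetype[d] == "lineage"])
    dc.head(2000).to_csv(args.out / "differential_correlation.tsv", sep="\t",
                         index=False)
    top = dc.iloc[0]
    print(f"strongest lineage-differential pair: {top['drug']} ~ {top['feature']} "
          f"(r_B = {top['r_a']:.2f}, r_T = {top['r_b']:.2f}, "
          f"|z| = {abs(top['z_difference']):.2f}, "
          f"analytic p = {top['p_analytic']:.2g})")


if __name__ == "__main__":
    main()
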