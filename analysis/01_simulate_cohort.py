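#!/usr/bin/env python
"""Generate the default synthetic cohort and write its fixtures.

Emits the protein and mRNA matrices (TSV), sample metadata, per-gene PSM
counts, the sDSS drug-response panel, and the ground-truth JSON that the
later analysis steps score themselves against.
"""

import argparse
from pathlib import Path

from leukomics.io import write_matrix, write_metadata
from leukomics.simulate import (DrugConfig, PsmConfig, SimulationConfig,
                                simulate_cohort, simulate_drug_response,
                                simulate_psm_counts)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--out", type=Path, default=Path("results/cohort"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cfg = SimulationConfig(seed=args.seed)
    protein, mrna, meta, truth = simulate_cohort(cfg)
    sdss = simulate_drug_response(protein, truth, DrugConfig(seed=args.seed))
    psm = simulate_psm_counts(protein, PsmConfig(seed=args.seed))

    write_matrix(protein, args.out / "protein_log2ratio.tsv")
    write_matrix(mrna, args.out / "mrna_log2tpm.tsv")
    write_metadata(meta, args.out / "sample_metadata.tsv")
    psm.rename_axis("gene").to_csv(args.out / "psm_counts.tsv", sep="\t")
    sdss.sdss.rename_axis("drug").to_csv(args.out / "sdss.tsv", sep="\t",
                                         na_rep="NA")
    truth.to_json(args.out / "truth.json")

    # drug annotations: the generator's target map in the standard TSV dialect
    with open(args.out / "drug_annotations.tsv", "w") as fh:
        fh.write("drug_id\tdrug_class\ttargets\tmechanism\n")
        for drug, arch in truth.drug_archetype.items():
            target = truth.drug_targets.get(drug, "")
            fh.write(f"{drug}\t{arch}\t{target}\tsynthetic {arch} archetype\n")
    # complex catalog
    with open(args.out / "complexes.tsv", "w") as fh:
        fh.write("complex_id\tname\tmembers\n")
        for cid, members in truth.complex_members.items():
            fh.write(f"{cid}\t{cid}\t{';'.join(members)}\n")

    print(f"cohort written to {args.out}")
    print(f"  genes={cfg.n_genes} samples={cfg.n_samples} "
          f"(+{cfg.n_replicates} replicates), HV genes={cfg.n_hv_genes}")
    print(f"  drugs={len(sdss.drug_ids)}, decoupling events="
          f"{len(truth.decoupling_events)}")


if __name__ == "__main__":
    main()
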