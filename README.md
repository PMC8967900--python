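# leukomics

Integrative proteome / transcriptome / drug-sensitivity analysis for
leukemia cell-line panels, built as a tested, reusable pipeline with a
ground-truthed synthetic cohort generator.

Multi-omic profiling of acute lymphoblastic leukemia (ALL) cell lines asks
a chain of statistical questions: which proteins vary enough across a panel
to carry phenotype (variable-feature selection); how tightly protein levels
track their transcripts (gene-wise mRNA–protein correlation); whether
protein complexes buffer their members' abundance beyond what transcripts
explain (complex co-regulation); which single samples break the
protein–mRNA relationship for particular genes (stability scores); how the
panel partitions into molecular subgroups (consensus clustering); what
distinguishes those subgroups (PSM-moderated differential abundance with
gene-set enrichment); and how baseline protein abundance explains drug
response (drug–protein correlation, target ranking, embedding, and
lineage-differential correlation). `leukomics` implements each stage as a
library function, wires them into numbered analysis drivers, and ships a
cohort generator whose planted ground truth lets every stage be scored
end-to-end with no external data.

It is written for computational biologists who want either the individual
statistical components (they accept plain `pandas`-backed matrices) or the
whole pipeline as a template for a real panel.

## The statistics at the core

* **Variable features.** Per-gene "quantile" SD (drop one min and one max
  observation, then sample SD); the SD distribution is modelled as a
  two-component Gaussian mixture fitted by EM, and the threshold t*
  maximises Σ_{s>t} [P(HV | s) − P(unmod | s)]. Ten seeded fits are
  averaged and floored to 0.5 for a reproducible cut.
* **Correlation.** Spearman's ρ per gene over pairwise-complete samples,
  p from t = ρ√(n−2)/√(1−ρ²) on n−2 df, BH q-values. Within-complex vs
  random-pair Pearson correlations compared by unpaired t-test; groups of
  correlations compared on the Fisher z = atanh(r) scale.
* **Stability scores.** Per gene, loess of protein log2 ratio on mRNA
  log2 TPM across samples; standardized residuals; |z| > 3 flags
  decoupling; complex-level events are mean member z per sample.
* **Consensus clustering.** 2000 rounds of 80%/80% sample/feature
  subsampling, hierarchical clustering on 1 − Pearson distance (Ward
  linkage), co-clustering frequencies, and k chosen from the delta-area of
  the consensus CDF; replicates inherit their parent's cluster.
* **Differential abundance.** Pooled per-gene variance shrunk toward a
  lowess trend of log s² on log min-PSM with empirical-Bayes prior df
  estimated from the log-F moments; moderated t on augmented df; flags at
  q ≤ 0.01 and |log2FC| ≥ log2(1.5). Preranked GSEA by the weighted
  Kolmogorov–Smirnov running sum with gene-label permutations.
* **Pharmacoproteomics.** Effective-drug filter (sDSS ≥ 8 in ≥ 2 lines),
  drug–protein/drug–drug Pearson matrices, putative-target ranks,
  PCA + UMAP embedding of drug correlation profiles, paired Fisher-z
  comparison of protein vs mRNA correlation strength, and two-group
  differential correlation via (z_A − z_B)/√(1/(n_A−3)+1/(n_B−3)) with
  analytic and permutation p-values.

See `docs/methods.md` for assumptions, parameter defaults, and limitations.

## Worked example

The numbered drivers run the whole pipeline on the default synthetic
cohort (3000 genes, 64 cell lines in 6 lineage-labelled groups, 300 planted
highly variable genes, 40 complexes, 40 drugs):

```bash
python analysis/01_simulate_cohort.py          # writes results/cohort/
python analysis/02_select_variable_features.py
python analysis/03_correlate_omics.py
python analysis/04_score_stability.py
python analysis/05_cluster_cohort.py
python analysis/06_differential_abundance.py
python analysis/07_pharmacoproteomics.py
```

Step 02 prints

```
run thresholds: [0.573, 0.573, 0.573, 0.573, 0.573, 0.573, 0.573, 0.573, 0.573, 0.573]
final threshold (floored to 0.5): 0.5
selected 332 HV proteins; recall=1.000 precision=0.904 against the 300 planted HV genes
```

— the ten EM runs agree on the variability threshold, the floored cut
keeps every planted highly variable gene and admits 32 false positives
from the unmodulated bulk's upper tail.

Step 03 prints

```
3000 genes correlated over 64 matched samples
median Spearman rho = 0.547; 99.9% positive, 91.3% significant at q <= 0.01
protein layer: within-complex mean r = 0.335 vs random 0.004 (n = 400 pairs each), t-test p = 2.97e-170
transcript layer: within-complex mean r = 0.001 vs random -0.007 (n = 400 pairs each), t-test p = 0.371
```

— the realized gene-wise mRNA–protein correlation matches the generator's
0.55 target, and complex co-regulation appears at the protein layer only,
exactly where the generator planted the shared latent factor.

Step 04 reports the planted complex collapse (4 members shifted −2 log2
units in one cell line):

```
complex CPX001 in planted sample CL026: mean z = -3.69 over 4 members
```

and step 07 ends the chain at the drug layer:

```
30 of 40 drugs effective (sDSS >= 8 in >= 2 cell lines)
putative targets at rank 1: 100% of 20 annotated target-driven drugs
strongest lineage-differential pair: DRUG_L002 ~ G00113 (r_B = -0.08, r_T = 0.83, |z| = 4.26, analytic p = 2.1e-05)
```

— every target-driven drug ranks its true target first among 3000
proteins, and the lineage-driven drugs surface as the strongest
differential correlations between B- and T-lineage samples.

## Layout

```
src/leukomics/     io, simulate, hvf, correlate, stability, cluster,
                   diffabund, pharmaco (+ shared _stats helpers)
analysis/          numbered narrative drivers over the library
tests/             unit, property, and end-to-end acceptance tests
scripts/           acceptance.py (see above)
docs/methods.md    models, defaults, generator design, limitations
```
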