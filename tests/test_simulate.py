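import numpy as np
import pandas as pd
import pytest
from scipy import stats

from leukomics.io import align_samples
from leukomics.simulate import (CohortTruth, DrugConfig, PsmConfig,
                                SimulationConfig, simulate_cohort,
                                simulate_drug_response, simulate_psm_counts)


class TestCohortGenerator:
    def test_same_seed_is_bit_identical(self):
        cfg = SimulationConfig(n_genes=200, n_samples=20, n_hv_genes=20,
                               n_complexes=5, seed=3)
        p1, m1, _, _ = simulate_cohort(cfg)
        p2, m2, _, _ = simulate_cohort(SimulationConfig(n_genes=200, n_samples=20,
                                                        n_hv_genes=20, n_complexes=5,
                                                        seed=3))
        pd.testing.assert_frame_equal(p1.values, p2.values)
        pd.testing.assert_frame_equal(m1.values, m2.values)

    def test_zero_missing_rate_gives_complete_matrix(self):
        cfg = SimulationConfig(n_genes=100, n_samples=12, n_hv_genes=10,
                               n_complexes=3, missing_rate=0.0, seed=0)
        protein, _, _, _ = simulate_cohort(cfg)
        assert not protein.values.isna().any().any()

    def test_infeasible_correlation_target_rejected(self):
        with pytest.raises(ValueError, match="median"):
            simulate_cohort(SimulationConfig(rho_median=1.0))

    def test_emitted_objects_share_sample_labels(self, default_cohort):
        protein = default_cohort["protein"]
        meta = default_cohort["meta"]
        truth = default_cohort["truth"]
        assert set(protein.sample_ids) == set(meta.sample_ids)
        assert set(protein.sample_ids) == set(truth.group_of)
        assert set(default_cohort["mrna"].sample_ids) <= set(meta.sample_ids)

    def test_realized_median_spearman_matches_target(self, collapsed_cohort):
        from leukomics.correlate import paired_feature_correlation
        tab = paired_feature_correlation(collapsed_cohort["protein"],
                                         collapsed_cohort["mrna"],
                                         method="spearman")
        assert abs(tab["r"].median() - 0.55) < 0.03

    def test_hv_genes_have_elevated_protein_sd(self, default_cohort):
        protein = default_cohort["protein"]
        truth = default_cohort["truth"]
        sds = protein.values.std(axis=1, ddof=1)
        hv = sds.loc[truth.hv_genes].median()
        rest = sds.drop(index=truth.hv_genes).median()
        assert hv / rest == pytest.approx(3.0, rel=0.1)

    def test_decoupling_events_shift_protein_only(self):
        cfg = SimulationConfig(n_genes=100, n_samples=30, n_hv_genes=0,
                               n_complexes=3, missing_rate=0.0,
                               n_replicates=0, seed=5)
        protein, mrna, _, truth = simulate_cohort(cfg)
        cfg2 = SimulationConfig(n_genes=100, n_samples=30, n_hv_genes=0,
                                n_complexes=3, missing_rate=0.0,
                                n_replicates=0, decoupling_events=[], seed=5)
        base, _, _, _ = simulate_cohort(cfg2)
        diff = protein.values - base.values
        for gene, sample, shift in truth.decoupling_events:
            assert diff.loc[gene, sample] == pytest.approx(shift)
        assert (diff != 0).sum().sum() == len(truth.decoupling_events)

    def test_truth_json_round_trip(self, tmp_path, default_cohort):
        truth = default_cohort["truth"]
        path = tmp_path / "truth.json"
        truth.to_json(path)
        back = CohortTruth.from_json(path)
        assert back.hv_genes == truth.hv_genes
        assert back.decoupling_events == truth.decoupling_events


class TestDrugResponse:
    def _cohort(self, seed, **kw):
        cfg = SimulationConfig(n_genes=300, n_samples=43, n_hv_genes=30,
                               n_complexes=5, n_replicates=0, seed=seed, **kw)
        return simulate_cohort(cfg)

    def test_target_driven_drug_correlates_with_target(self):
        hits = 0
        n_seeds = 25
        for seed in range(n_seeds):
            protein, _, _, truth = self._cohort(seed)
            sdss = simulate_drug_response(
                protein, truth, DrugConfig(seed=seed, n_target_drugs=2,
                                           n_lineage_drugs=0, n_toxic_drugs=0,
                                           n_inactive_drugs=0))
            for drug, gene in truth.drug_targets.items():
                x = protein.values.loc[gene].to_numpy()
                y = sdss.sdss.loc[drug].to_numpy()
                ok = np.isfinite(x) & np.isfinite(y)
                r = stats.pearsonr(x[ok], y[ok]).statistic
                hits += r > 0.6
        assert hits / (2 * n_seeds) >= 0.95

    def test_zero_slope_gives_null_correlation(self):
        protein, _, _, truth = self._cohort(1)
        sdss = simulate_drug_response(
            protein, truth, DrugConfig(seed=1, target_slope=0.0,
                                       n_target_drugs=30, n_lineage_drugs=0,
                                       n_toxic_drugs=0, n_inactive_drugs=0))
        rs = []
        for drug, gene in truth.drug_targets.items():
            x = protein.values.loc[gene].to_numpy()
            y = sdss.sdss.loc[drug].to_numpy()
            ok = np.isfinite(x) & np.isfinite(y)
            rs.append(stats.pearsonr(x[ok], y[ok]).statistic)
        assert abs(np.mean(rs)) < 0.15

    def test_lineage_offset_recovered(self):
        protein, _, meta, truth = self._cohort(2)
        sdss = simulate_drug_response(
            protein, truth, DrugConfig(seed=2, n_target_drugs=0,
                                       n_lineage_drugs=2, lineage_offset=10.0,
                                       n_toxic_drugs=0, n_inactive_drugs=0))
        for drug, lin in truth.lineage_drugs.items():
            vals = sdss.sdss.loc[drug]
            in_lin = [s for s in vals.index if truth.lineage_of[s] == lin]
            out_lin = [s for s in vals.index if truth.lineage_of[s] != lin]
            diff = vals[in_lin].mean() - vals[out_lin].mean()
            assert diff == pytest.approx(10.0, abs=2.0)


class TestPsmCounts:
    def test_counts_are_nonnegative_integers_and_reproducible(self, default_cohort):
        psm1 = simulate_psm_counts(default_cohort["protein"], PsmConfig(seed=4))
        psm2 = simulate_psm_counts(default_cohort["protein"], PsmConfig(seed=4))
        pd.testing.assert_frame_equal(psm1, psm2)
        assert (psm1.to_numpy() >= 0).all()
        assert np.issubdtype(psm1.to_numpy().dtype, np.integer)

    def test_variance_decreases_across_min_psm_bins(self, default_cohort):
        protein = default_cohort["protein"]
        psm = simulate_psm_counts(protein, PsmConfig(seed=0))
        counts = psm.to_numpy(dtype=float)
        counts[counts == 0] = np.nan
        min_psm = np.nanmin(counts, axis=1)
        var = protein.values.var(axis=1, ddof=1).to_numpy()
        ok = np.isfinite(min_psm) & np.isfinite(var)
        bins = pd.qcut(min_psm[ok], 4, duplicates="drop")
        medians = pd.Series(var[ok]).groupby(bins, observed=True).median()
        assert (medians.diff().dropna() < 0).all()
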