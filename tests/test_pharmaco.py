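import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import cdist

from conftest import make_matrix
from leukomics.io import (DrugAnnotation, DrugResponseMatrix, OmicsMatrix,
                          align_samples)
from leukomics.pharmaco import (compare_protein_vs_rna_correlation,
                                differential_correlation,
                                drug_drug_correlations,
                                drug_feature_correlations,
                                embed_drug_profiles, filter_effective_drugs)
from leukomics.simulate import (DrugConfig, SimulationConfig, simulate_cohort,
                                simulate_drug_response)


def drug_matrix(rows, drugs=None, samples=None):
    rows = np.asarray(rows, dtype=float)
    drugs = drugs or [f"D{i + 1}" for i in range(rows.shape[0])]
    samples = samples or [f"S{i + 1}" for i in range(rows.shape[1])]
    return DrugResponseMatrix(pd.DataFrame(rows, index=drugs, columns=samples))


class TestEffectiveDrugFilter:
    def test_all_below_threshold_gives_empty_list(self):
        sdss = drug_matrix(np.full((3, 5), 4.0))
        assert filter_effective_drugs(sdss) == []

    def test_rule_forced_example(self):
        sdss = drug_matrix([[9.0, 7.0, 8.0]])
        assert filter_effective_drugs(sdss, threshold=8, min_lines=2) == ["D1"]

    def test_missing_never_qualifies(self):
        sdss = drug_matrix([[9.0, np.nan, np.nan]])
        assert filter_effective_drugs(sdss, threshold=8, min_lines=2) == []

    def test_monotone_in_threshold_and_min_lines(self):
        rng = np.random.default_rng(0)
        sdss = drug_matrix(rng.normal(6, 4, (40, 20)))
        base = set(filter_effective_drugs(sdss, threshold=8, min_lines=2))
        assert set(filter_effective_drugs(sdss, threshold=10, min_lines=2)) <= base
        assert set(filter_effective_drugs(sdss, threshold=8, min_lines=4)) <= base


class TestDrugFeatureCorrelations:
    def test_identical_profile_ranks_first(self):
        rng = np.random.default_rng(1)
        feats = rng.normal(0, 1, (20, 15))
        sdss = drug_matrix(feats[3][None, :] * 2.0 + 5.0)  # affine in G4
        features = make_matrix(feats)
        ann = DrugAnnotation(pd.DataFrame(
            {"drug_class": ["x"], "targets": [["G4"]], "mechanism": [""]},
            index=pd.Index(["D1"], name="drug_id")))
        res = drug_feature_correlations(sdss, features, annotations=ann)
        assert res.r.loc["D1", "G4"] == pytest.approx(1.0)
        assert res.top_features["D1"][0] == "G4"
        assert res.target_ranks.iloc[0]["rank"] == 1

    def test_low_overlap_entries_missing_and_unranked(self):
        rng = np.random.default_rng(2)
        feats = rng.normal(0, 1, (3, 15))
        feats[0, 5:] = np.nan  # 5 complete pairs < min_n
        sdss = drug_matrix(rng.normal(0, 1, (1, 15)))
        res = drug_feature_correlations(sdss, make_matrix(feats), min_n=10)
        assert np.isnan(res.r.loc["D1", "G1"])
        assert "G1" not in res.top_features["D1"]

    def test_planted_target_recovered(self, ):
        protein, _, _, truth = simulate_cohort(
            SimulationConfig(seed=0, n_genes=2000, n_samples=43, n_replicates=0))
        sdss = simulate_drug_response(protein, truth,
                                      DrugConfig(seed=0, n_target_drugs=5,
                                                 n_lineage_drugs=0,
                                                 n_toxic_drugs=0,
                                                 n_inactive_drugs=0))
        sdss_a, prot_a, _ = align_samples(sdss, protein)
        res = drug_feature_correlations(sdss_a, prot_a)
        hits = sum(res.top_features[d][0] == g
                   for d, g in truth.drug_targets.items())
        assert hits >= 4


class TestDrugDrugCorrelations:
    def test_duplicated_drug_correlates_perfectly(self):
        rng = np.random.default_rng(3)
        profile = rng.normal(0, 3, 20)
        sdss = drug_matrix([profile, profile, rng.normal(0, 3, 20)])
        tab = drug_drug_correlations(sdss)
        pair = tab[(tab["drug_a"] == "D1") & (tab["drug_b"] == "D2")]
        assert pair["r"].iloc[0] == pytest.approx(1.0)

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(4)
        sdss = drug_matrix(rng.normal(0, 1, (46, 30)))
        tab = drug_drug_correlations(sdss)
        assert len(tab) == 46 * 45 / 2
        assert stats.kstest(tab["p"], "uniform").pvalue > 0.01

    def test_shared_target_drugs_correlate(self):
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            target = rng.normal(0, 0.45 * 3, 43)
            d1 = 6 * target + rng.normal(0, 2, 43)
            d2 = 6 * target + rng.normal(0, 2, 43)
            tab = drug_drug_correlations(drug_matrix([d1, d2]))
            hits += tab["r"].iloc[0] > 0.6
        assert hits / n_seeds >= 0.95


class TestProteinVsRnaComparison:
    def test_identical_layers_give_null_result(self):
        rng = np.random.default_rng(5)
        feats = rng.normal(0, 1, (20, 25))
        prot = make_matrix(feats)
        mrna = make_matrix(feats, kind="mrna_log2tpm")
        sdss = drug_matrix(rng.normal(0, 3, (5, 25)))
        res = compare_protein_vs_rna_correlation(sdss, prot, mrna)
        assert res.mean_z_difference == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_protein_driven_drugs_favor_protein_layer(self):
        # a latent program drives protein levels and drug response; mRNA is a
        # noisier copy, so every drug-gene correlation is attenuated there
        rng = np.random.default_rng(6)
        latent = rng.normal(0, 1, 30)
        prot_vals = latent[None, :] + rng.normal(0, 0.5, (40, 30))
        mrna_vals = prot_vals + rng.normal(0, 1.5, (40, 30))
        drugs = np.array([4 * latent + rng.normal(0, 1, 30)
                          for _ in range(10)])
        res = compare_protein_vs_rna_correlation(
            drug_matrix(drugs), make_matrix(prot_vals),
            make_matrix(mrna_vals, kind="mrna_log2tpm"))
        assert res.mean_z_difference > 0
        assert res.p_value < 1e-6

    def test_swapping_layers_reverses_direction(self):
        rng = np.random.default_rng(7)
        prot_vals = rng.normal(0, 1, (15, 25))
        mrna_vals = rng.normal(0, 1, (15, 25))
        sdss = drug_matrix(rng.normal(0, 2, (4, 25)))
        prot = make_matrix(prot_vals)
        mrna = make_matrix(mrna_vals, kind="mrna_log2tpm")
        fwd = compare_protein_vs_rna_correlation(sdss, prot, mrna)
        rev = compare_protein_vs_rna_correlation(sdss, mrna, prot)
        assert fwd.mean_z_difference == pytest.approx(-rev.mean_z_difference)
        assert abs(fwd.statistic) == pytest.approx(abs(rev.statistic))


class TestEmbedding:
    def test_geometry_determinism_and_duplicates(self):
        rng = np.random.default_rng(8)
        nfeat = 200
        prog1 = np.zeros(nfeat)
        prog1[:40] = 1.0
        prog2 = np.zeros(nfeat)
        prog2[40:80] = 1.0
        rows = ([prog1 * 0.8 + rng.normal(0, 0.1, nfeat) for _ in range(20)]
                + [prog2 * 0.8 + rng.normal(0, 0.1, nfeat) for _ in range(20)])
        rows.append(rows[0])  # duplicated drug profile
        corr = pd.DataFrame(rows, index=[f"D{i}" for i in range(41)])
        corr.iloc[5, :3] = np.nan  # missing correlations are imputed
        emb = embed_drug_profiles(corr, n_pcs=10, seed=0)
        assert emb.coordinates.shape == (41, 2)
        assert np.isfinite(emb.coordinates.to_numpy()).all()
        assert emb.n_imputed == 3

        # same seed -> identical coordinates
        emb2 = embed_drug_profiles(corr, n_pcs=10, seed=0)
        pd.testing.assert_frame_equal(emb.coordinates, emb2.coordinates)

        co = emb.coordinates.to_numpy()[:40]
        d = cdist(co, co)
        within = np.concatenate([d[:20, :20][np.triu_indices(20, 1)],
                                 d[20:, 20:][np.triu_indices(20, 1)]])
        between = d[:20, 20:].ravel()
        assert within.mean() < between.mean()

        # duplicated drug lands nearly on top of its twin
        full = emb.coordinates.to_numpy()
        dup_dist = np.linalg.norm(full[40] - full[0])
        all_d = cdist(full, full)[np.triu_indices(41, 1)]
        assert dup_dist < np.percentile(all_d, 1)

    def test_n_pcs_clamped(self):
        rng = np.random.default_rng(9)
        corr = pd.DataFrame(rng.normal(0, 1, (12, 30)),
                            index=[f"D{i}" for i in range(12)])
        emb = embed_drug_profiles(corr, n_pcs=27, n_neighbors=25, seed=0)
        assert emb.n_pcs == 11
        assert emb.params["n_neighbors"] == 11


class TestDifferentialCorrelation:
    def _pair(self, r_a, r_b, n=30, seed=0, scale=1.0):
        rng = np.random.default_rng(seed)
        lat = rng.normal(0, 1, 2 * n)
        feat = np.empty(2 * n)
        feat[:n] = r_a * lat[:n] + np.sqrt(1 - r_a ** 2) * rng.normal(0, 1, n)
        feat[n:] = r_b * lat[n:] + np.sqrt(1 - r_b ** 2) * rng.normal(0, 1, n)
        samples = [f"S{i}" for i in range(2 * n)]
        fv = make_matrix(scale * feat[None, :] + 5.0, samples=samples)
        dv = drug_matrix(3 * lat[None, :] + 5.0, samples=samples)
        grouping = {f"S{i}": ("A" if i < n else "B") for i in range(2 * n)}
        return dv, fv, grouping

    def test_closed_form_fisher_z_example(self):
        # r_A = 0.7, r_B = 0.0, n = 30 each -> z ~ 3.19, p ~ 0.0014
        from leukomics._stats import fisher_z_difference
        z = float(fisher_z_difference(0.7, 30, 0.0, 30))
        assert z == pytest.approx(3.19, abs=0.01)
        p = 2 * stats.norm.sf(abs(z))
        assert p == pytest.approx(0.0014, abs=1e-4)

    def test_null_identity_structure(self):
        dv, fv, grouping = self._pair(0.6, 0.6, n=40, seed=1)
        tab = differential_correlation(dv, fv, grouping, n_perm=200, seed=0,
                                       exclude_zero=False)
        row = tab.iloc[0]
        assert abs(row["z_difference"]) < 2.5
        assert row["class"] in {"+/+", "+/0", "0/+", "0/0"}

    def test_opposite_sign_pair_detected_and_classified(self):
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            dv, fv, grouping = self._pair(0.6, -0.6, n=25, seed=seed)
            tab = differential_correlation(dv, fv, grouping, n_perm=50,
                                           seed=seed, exclude_zero=False)
            row = tab.iloc[0]
            hits += (row["p_analytic"] < 0.01) and row["class"] == "+/-"
        assert hits / n_seeds >= 0.9

    def test_zero_values_excluded_when_configured(self):
        dv, fv, grouping = self._pair(0.5, 0.5, n=20, seed=3)
        fv.values.iloc[0, :4] = 0.0
        tab = differential_correlation(dv, fv, grouping, n_perm=10, seed=0,
                                       exclude_zero=True)
        assert tab.iloc[0]["n_a"] == 16

    def test_small_groups_rejected(self):
        dv, fv, grouping = self._pair(0.5, 0.5, n=5, seed=4)
        with pytest.raises(ValueError, match=">= 10"):
            differential_correlation(dv, fv, grouping, n_perm=10, seed=0)
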