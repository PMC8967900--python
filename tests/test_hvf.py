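import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_matrix
from leukomics.hvf import (MixtureFit, fit_two_component_mixture, floor_to_half,
                           optimal_threshold, quantile_sd, select_hvf)


def oracle_quantile_sd(values):
    """Independent sort-trim-SD oracle."""
    v = sorted(x for x in values if np.isfinite(x))
    if len(v) < 4:
        return np.nan
    trimmed = v[1:-1]
    return float(np.std(trimmed, ddof=1))


class TestQuantileSD:
    @pytest.mark.parametrize("values, expected", [
        ([5, 5, 5, 5, 5], 0.0),
        ([1, 2, 3, 4, 10], 1.0),
    ])
    def test_known_values(self, values, expected):
        assert quantile_sd(np.array(values, dtype=float)) == pytest.approx(expected)

    def test_insufficient_data_is_missing(self):
        assert np.isnan(quantile_sd(np.array([1.0, 2.0, np.nan])))
        assert np.isnan(quantile_sd(np.array([1.0])))

    @given(st.lists(st.floats(-50, 50), min_size=0, max_size=30),
           st.integers(0, 5))
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_matches_oracle_with_missing(self, values, n_missing):
        arr = np.array(values + [np.nan] * n_missing, dtype=float)
        got = quantile_sd(arr)
        want = oracle_quantile_sd(arr)
        if np.isnan(want):
            assert np.isnan(got)
        else:
            assert got == pytest.approx(want, abs=1e-12)


class TestMixtureEM:
    def test_recovers_generating_parameters(self):
        rng = np.random.default_rng(10)
        comp = rng.random(5000) < 0.8
        x = np.where(comp, rng.normal(0.30, 0.05, 5000),
                     rng.normal(0.90, 0.10, 5000))
        fit = fit_two_component_mixture(x, seed=0)
        assert fit.means[0] == pytest.approx(0.30, abs=0.02)
        assert fit.means[1] == pytest.approx(0.90, abs=0.02)
        assert fit.weights[0] == pytest.approx(0.80, abs=0.03)
        assert fit.converged

    def test_log_likelihood_non_decreasing(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(0, 1, 300), rng.normal(5, 1, 100)])
        fit = fit_two_component_mixture(x, seed=2)
        trace = np.array(fit.ll_trace)
        assert (np.diff(trace) >= -1e-9).all()

    def test_responsibilities_sum_to_one(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(0, 1, 200), rng.normal(4, 1, 100)])
        fit = fit_two_component_mixture(x, seed=0)
        resp = fit.responsibilities(x)
        np.testing.assert_allclose(resp.sum(axis=1), 1.0, atol=1e-12)

    def test_identical_values_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_two_component_mixture(np.full(100, 0.7), seed=0)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="20"):
            fit_two_component_mixture(np.arange(10, dtype=float), seed=0)

    def test_single_component_split_flagged_by_separation(self):
        # a single well-separated-from-nothing component: the 2-component fit
        # splits it roughly in half and the separation diagnostic is low
        rng = np.random.default_rng(3)
        x = rng.normal(1.0, 0.1, 2000)
        fit = fit_two_component_mixture(x, seed=1)
        assert fit.separation < 2.0

    def test_agrees_with_sklearn_gmm(self):
        # independent mixture-fit oracle on the same data
        from sklearn.mixture import GaussianMixture
        rng = np.random.default_rng(4)
        comp = rng.random(3000) < 0.7
        x = np.where(comp, rng.normal(0.3, 0.05, 3000), rng.normal(1.0, 0.15, 3000))
        fit = fit_two_component_mixture(x, seed=0)
        gm = GaussianMixture(2, random_state=0, n_init=3).fit(x[:, None])
        order = np.argsort(gm.means_.ravel())
        np.testing.assert_allclose(fit.means, gm.means_.ravel()[order], atol=0.01)
        np.testing.assert_allclose(fit.weights, gm.weights_[order], atol=0.02)


class TestThreshold:
    def _fit(self, mu, sd, w):
        return MixtureFit(means=mu, sds=sd, weights=w, log_likelihood=0.0,
                          n_iterations=1, converged=True)

    def test_perfect_separation_returns_smallest_attaining_t(self):
        fit = self._fit((0.0, 10.0), (0.5, 0.5), (0.5, 0.5))
        low = np.array([-0.5, 0.0, 0.5])
        high = np.array([9.5, 10.0, 10.5])
        t = optimal_threshold(fit, np.concatenate([low, high]))
        assert t == 0.5  # the largest low-component value: smallest t with max objective

    def test_matches_brute_force_on_small_vector(self):
        rng = np.random.default_rng(5)
        sds = np.concatenate([rng.normal(0.4, 0.1, 30), rng.normal(1.2, 0.2, 20)])
        fit = fit_two_component_mixture(
            np.concatenate([rng.normal(0.4, 0.1, 500), rng.normal(1.2, 0.2, 300)]),
            seed=0)
        t = optimal_threshold(fit, sds)
        # brute force: evaluate the objective on the same grid directly
        x = np.sort(sds)
        grid = np.unique(np.concatenate([x, (x[:-1] + x[1:]) / 2]))
        resp = fit.responsibilities(x)

        def objective(thr):
            sel = x > thr
            return (resp[sel, 1] - resp[sel, 0]).sum()

        objs = np.array([objective(g) for g in grid])
        best = grid[np.flatnonzero(objs >= objs.max() - 1e-12)[0]]
        assert t == pytest.approx(best)

    def test_no_hv_mass_gives_empty_hv_set(self):
        fit = self._fit((0.5, 50.0), (0.1, 0.1), (1 - 1e-9, 1e-9))
        sds = np.linspace(0.2, 0.8, 50)
        t = optimal_threshold(fit, sds)
        assert t >= sds.max()
        assert not (sds > t).any()

    @pytest.mark.parametrize("mean, expected", [(1.26, 1.0), (1.62, 1.5)])
    def test_floor_rule(self, mean, expected):
        assert floor_to_half(mean) == expected


class TestSelectHVF:
    def test_recovers_planted_hv_set(self, default_cohort):
        from leukomics.io import collapse_replicates
        protein = collapse_replicates(default_cohort["protein"],
                                      default_cohort["meta"])
        res = select_hvf(protein, n_runs=5, seed=11)
        truth = set(default_cohort["truth"].hv_genes)
        est = set(res.hv_features)
        recall = len(truth & est) / len(truth)
        precision = len(truth & est) / max(len(est), 1)
        assert recall >= 0.9
        assert precision >= 0.8

    def test_reproducible_under_master_seed(self, default_cohort):
        protein = default_cohort["protein"]
        r1 = select_hvf(protein, n_runs=3, seed=5)
        r2 = select_hvf(protein, n_runs=3, seed=5)
        assert r1.final_threshold == r2.final_threshold
        assert r1.hv_features == r2.hv_features

    def test_hv_set_monotone_in_threshold(self, default_cohort):
        protein = default_cohort["protein"]
        res = select_hvf(protein, n_runs=2, seed=1)
        sds = res.quantile_sds
        low = {f for f, s in zip(res.feature_ids, sds)
               if np.isfinite(s) and s > res.final_threshold - 0.5}
        high = {f for f, s in zip(res.feature_ids, sds)
                if np.isfinite(s) and s > res.final_threshold + 0.5}
        assert high <= set(res.hv_features) <= low
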