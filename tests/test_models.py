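"""Generative drift models, likelihood scan, and classification rules."""

import numpy as np
import pytest

from szpath import (
    ModelLikelihoods,
    ModelParams,
    basis_functions,
    classify_dynamics,
    compute_tcp,
    likelihood_scan,
    simulate_dissimilarity,
    simulate_tcp_ensemble,
    tcp_mse,
    temporal_distances,
)
from szpath.models import simplex_grid


class TestBasisFunctions:
    def test_linear_slope_one_per_week(self):
        fl, _ = basis_functions([0.0, 7.0])
        assert fl[0] == 0.0 and fl[1] == 1.0

    def test_circadian_quarter_and_half_day(self):
        _, fc = basis_functions([0.25, 0.5])
        assert np.isclose(fc[0], 1.0, atol=1e-12)
        assert np.isclose(fc[1], 0.0, atol=1e-12)

    @pytest.mark.parametrize("t", [0.1, 0.3, 0.9])
    def test_circadian_period_one_day(self, t):
        _, fc = basis_functions([t, t + 1.0])
        assert np.isclose(fc[0], fc[1], atol=1e-9)


class TestSimulateDissimilarity:
    def test_pure_linear_week_apart(self):
        D = simulate_dissimilarity(np.array([0.0, 7.0]), ModelParams(1, 0, 0))
        assert np.isclose(D[0, 1], 1.0)

    def test_pure_circadian_closed_form(self):
        D = simulate_dissimilarity(np.array([0.0, 0.25, 0.5]), ModelParams(0, 1, 0))
        assert np.isclose(D[0, 1], 1.0) and np.isclose(D[1, 2], 1.0)
        assert np.isclose(D[0, 2], 0.0, atol=1e-12)

    def test_combined_integer_days_sine_vanishes(self):
        D = simulate_dissimilarity(np.array([0.0, 7.0]), ModelParams(1, 1, 0))
        assert np.isclose(D[0, 1], 1.0, atol=1e-9)

    def test_symmetric_zero_diagonal(self):
        t = np.sort(np.random.default_rng(0).uniform(0, 5, 8))
        D = simulate_dissimilarity(t - t[0], ModelParams(0.5, 0.3, 0.2, seed=1))
        assert np.allclose(D, D.T) and np.all(np.diag(D) == 0)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            ModelParams(0, 0, 0)


@pytest.fixture(scope="module")
def times12():
    rng = np.random.default_rng(99)
    t = np.sort(rng.uniform(0, 7, 12))
    return t - t[0]


class TestEnsemble:
    def test_noise_free_patterns_identical(self, times12):
        ens = simulate_tcp_ensemble(times12, ModelParams(1, 0, 0), n_sims=50)
        assert np.allclose(ens.rho, ens.rho[0], equal_nan=True)

    def test_pure_linear_rho_one(self, times12):
        ens = simulate_tcp_ensemble(times12, ModelParams(1, 0, 0), n_sims=3)
        assert np.allclose(ens.rho[:, ens.valid], 1.0)

    def test_pure_noise_rho_centred_on_zero(self, times12):
        ens = simulate_tcp_ensemble(times12, ModelParams(0, 0, 1), n_sims=200, seed=0)
        means = np.nanmean(ens.rho[:, ens.valid], axis=0)
        assert np.all(np.abs(means) < 0.1)

    def test_circadian_short_timescales_correlate_more(self, times12):
        ens = simulate_tcp_ensemble(times12, ModelParams(0, 1, 0), n_sims=1)
        grid, rho = ens.timescales, ens.rho[0]
        short = ens.valid & (grid < 1.0)
        longer = ens.valid & (grid > 2.0)
        assert np.nanmean(rho[short]) > np.nanmean(rho[longer])

    def test_seeded_reproducibility(self, times12):
        a = simulate_tcp_ensemble(times12, ModelParams(0.5, 0.3, 0.2), n_sims=20, seed=4)
        b = simulate_tcp_ensemble(times12, ModelParams(0.5, 0.3, 0.2), n_sims=20, seed=4)
        assert np.array_equal(a.rho, b.rho, equal_nan=True)

    def test_scale_invariance_of_patterns(self, times12):
        a = simulate_tcp_ensemble(times12, ModelParams(0.4, 0.4, 0.2), n_sims=20, seed=8)
        b = simulate_tcp_ensemble(times12, ModelParams(2.0, 2.0, 1.0), n_sims=20, seed=8)
        assert np.allclose(a.rho, b.rho, equal_nan=True)


class TestTcpMse:
    def _observed(self, times):
        D = simulate_dissimilarity(times, ModelParams(1, 0, 0))
        TD = temporal_distances(times)
        return compute_tcp(D, TD)

    def test_identical_patterns_zero(self, times12):
        obs = self._observed(times12)
        ens = simulate_tcp_ensemble(times12, ModelParams(1, 0, 0), n_sims=2)
        assert np.allclose(tcp_mse(obs, ens), 0.0)

    def test_constant_offset(self, times12):
        obs = self._observed(times12)
        shifted = obs.rho - 0.1
        assert np.isclose(tcp_mse(obs, shifted, obs.valid)[0], 0.01)

    def test_masked_timescales_excluded(self, times12):
        obs = self._observed(times12)
        sim = obs.rho.copy()
        sim[~obs.valid] = 99.0  # garbage outside the valid mask is ignored
        assert np.isclose(tcp_mse(obs, sim, obs.valid)[0], 0.0)

    def test_no_common_timescales_rejected(self, times12):
        obs = self._observed(times12)
        with pytest.raises(ValueError, match="mutually valid"):
            tcp_mse(obs, np.full((1, obs.timescales.size), np.nan), np.zeros_like(obs.valid))


class TestLikelihoodScan:
    def test_grid_covers_all_classes(self):
        cells = simplex_grid()
        classes = {ModelParams(*c).model_class for c in cells if any(c)}
        assert classes == {"linear", "circadian", "combined", "noise"}
        assert (0.0, 0.0, 1.0) in cells and (1.0, 0.0, 0.0) in cells

    def test_exact_linear_match_scores_100(self, times12):
        D = simulate_dissimilarity(times12, ModelParams(1, 0, 0))
        TD = temporal_distances(times12)
        obs = compute_tcp(D, TD)
        ml = likelihood_scan(obs, times12, n_sims=50, seed=0)
        assert ml.L_l == 100.0
        for L in (ml.L_l, ml.L_c, ml.L_lc, ml.L_n):
            assert 0.0 <= L <= 100.0

    def test_empty_class_rejected(self, times12):
        D = simulate_dissimilarity(times12, ModelParams(1, 0, 0))
        obs = compute_tcp(D, temporal_distances(times12))
        with pytest.raises(ValueError, match="no cells"):
            likelihood_scan(obs, times12, grid=[(1.0, 0.0, 0.0)], n_sims=10)


class TestClassification:
    def _ml(self, L_l, L_c, L_lc, L_n):
        return ModelLikelihoods(
            L_l=L_l, L_c=L_c, L_lc=L_lc, L_n=L_n, best_params={}, mse_threshold=0.02185
        )

    def test_combined_falls_back_to_comparable_linear(self):
        cls = classify_dynamics(self._ml(60, 5, 65, 10))
        assert cls.label == "linear"
        assert any("comparably" in r for r in cls.rationale)

    def test_noise_not_outperformed(self):
        assert classify_dynamics(self._ml(15, 2, 10, 10)).label == "other/indeterminate"

    def test_unseparated_simple_models(self):
        assert classify_dynamics(self._ml(40, 30, 50, 5)).label == "other/indeterminate"

    def test_dominant_combined(self):
        assert classify_dynamics(self._ml(20, 25, 80, 5)).label == "linear+circadian"

    def test_clear_circadian(self):
        assert classify_dynamics(self._ml(10, 70, 75, 5)).label == "circadian"

    def test_all_zero_indeterminate(self):
        assert classify_dynamics(self._ml(0, 0, 0, 0)).label == "other/indeterminate"

    def test_decision_reproducible_from_likelihoods(self):
        ml = self._ml(60, 5, 65, 10)
        assert classify_dynamics(ml).label == classify_dynamics(ml).label
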