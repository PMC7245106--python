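"""Temporal distances, Mantel test, FDR, and timescale scans."""

from itertools import permutations

import numpy as np
import pytest
from scipy.stats import spearmanr

from szpath import (
    bh_fdr,
    compute_tcp,
    dissimilarity_matrix,
    mantel_spearman,
    temporal_distances,
)


class TestTemporalDistances:
    def test_pairwise_elapsed_days(self):
        td = temporal_distances(np.array([0.0, 0.5, 2.0]))
        iu = np.triu_indices(3, k=1)
        assert sorted(td.values[iu]) == [0.5, 1.5, 2.0]

    def test_single_pair(self):
        td = temporal_distances(np.array([0.0, 5.0]))
        assert td.values[0, 1] == 5.0

    def test_non_day_units_rejected(self):
        with pytest.raises(ValueError, match="days"):
            temporal_distances(np.array([0.0, 12.0, 24.0]), units="hours")

    def test_duplicates_flagged(self):
        with pytest.warns(UserWarning, match="duplicate"):
            td = temporal_distances(np.array([0.0, 1.0, 1.0]))
        assert td.has_duplicates

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            temporal_distances(np.array([0.0, 2.0, 1.0]))


def _random_instance(S, seed):
    rng = np.random.default_rng(seed)
    t = np.sort(rng.uniform(0, 10, S))
    t -= t[0]
    TD = temporal_distances(t)
    pts = rng.uniform(size=S)
    D = np.abs(pts[:, None] - pts[None, :])
    return D, TD


class TestMantel:
    def test_monotone_relation_gives_rho_one(self):
        t = np.array([0.0, 1.0, 2.5, 4.0, 7.0])
        TD = temporal_distances(t)
        D = TD.values**2  # strictly increasing transform preserves ranks
        res = mantel_spearman(D, TD, n_perm=99, seed=0)
        assert np.isclose(res.rho, 1.0)

    def test_exhaustive_matches_explicit_enumeration(self):
        """Oracle: recompute every relabelling with scipy's spearmanr."""
        D, TD = _random_instance(4, seed=7)
        res = mantel_spearman(D, TD, mode="exhaustive")
        iu = np.triu_indices(4, k=1)
        obs = spearmanr(TD.values[iu], D[iu]).statistic
        count = 0
        for p in permutations(range(4)):
            p = list(p)
            rho_p = spearmanr(TD.values[iu], D[np.ix_(p, p)][iu]).statistic
            count += rho_p >= obs - 1e-12
        assert np.isclose(res.rho, obs)
        assert res.n_perm == 24
        assert np.isclose(res.p, count / 24)

    def test_identity_case_exhaustive(self):
        t = np.array([0.0, 1.0, 3.0, 6.0])
        TD = temporal_distances(t)
        res = mantel_spearman(TD.values.copy(), TD, mode="exhaustive")
        assert np.isclose(res.rho, 1.0)
        iu = np.triu_indices(4, k=1)
        count = sum(
            spearmanr(TD.values[iu], TD.values[np.ix_(list(p), list(p))][iu]).statistic
            >= 1 - 1e-12
            for p in permutations(range(4))
        )
        assert np.isclose(res.p, count / 24)

    def test_relabelling_invariance(self):
        D, TD = _random_instance(8, seed=3)
        perm = np.random.default_rng(0).permutation(8)
        res1 = mantel_spearman(D, TD.values, n_perm=500, seed=9)
        res2 = mantel_spearman(
            D[np.ix_(perm, perm)], TD.values[np.ix_(perm, perm)], n_perm=500, seed=9
        )
        assert np.isclose(res1.rho, res2.rho)
        assert abs(res1.p - res2.p) < 0.05

    def test_constant_matrix_flagged(self):
        t = np.array([0.0, 1.0, 2.0, 3.0])
        TD = temporal_distances(t)
        res = mantel_spearman(np.zeros((4, 4)), TD, n_perm=10)
        assert not res.valid and np.isnan(res.rho)

    def test_agrees_with_skbio(self):
        """Independent cross-check against scikit-bio's Mantel test."""
        from skbio.stats.distance import DistanceMatrix, mantel

        D, TD = _random_instance(10, seed=21)
        ours = mantel_spearman(D, TD, n_perm=3000, seed=0, smoothed=True)
        rho_sk, p_sk, _ = mantel(
            DistanceMatrix(D),
            DistanceMatrix(TD.values),
            method="spearman",
            permutations=3000,
            alternative="greater",
        )
        assert np.isclose(ours.rho, rho_sk, atol=1e-12)
        assert abs(ours.p - p_sk) < 0.05

    def test_smoothed_estimator_variant(self):
        D, TD = _random_instance(6, seed=5)
        raw = mantel_spearman(D, TD, n_perm=200, seed=1, smoothed=False)
        smooth = mantel_spearman(D, TD, n_perm=200, seed=1, smoothed=True)
        assert np.isclose(smooth.p, (raw.p * 200 + 1) / 201)


class TestFdr:
    def test_single_p_unchanged(self):
        adj, flags = bh_fdr([0.01])
        assert np.isclose(adj[0], 0.01) and flags[0]

    def test_step_up_hand_computed(self):
        adj, _ = bh_fdr([0.01, 0.02, 0.03])
        assert np.allclose(adj, [0.03, 0.03, 0.03])

    def test_all_ones_never_significant(self):
        adj, flags = bh_fdr([1.0, 1.0, 1.0])
        assert not flags.any()

    def test_nan_excluded(self):
        adj, flags = bh_fdr([0.01, np.nan, 0.5])
        assert np.isnan(adj[1]) and not flags[1]
        assert flags[0]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([])


class TestTcp:
    def test_noiseless_linear_cohort_rho_one_everywhere(self, linear_cohort):
        D = dissimilarity_matrix(linear_cohort.seizures)
        TD = temporal_distances(linear_cohort.times)
        tcp = compute_tcp(D, TD, min_pairs=7)
        assert tcp.any_valid
        assert np.allclose(tcp.rho[tcp.valid], 1.0)

    def test_min_pairs_masking(self):
        t = np.array([0.0, 0.1, 0.2, 3.0, 3.1, 3.2])
        TD = temporal_distances(t)
        D = TD.values + 0.01 * np.random.default_rng(0).uniform(size=(6, 6))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        tcp = compute_tcp(D, TD, min_pairs=7)
        # at T=0.25 only 6 pairs exist (two triplets): masked
        assert not tcp.valid[0]

    def test_plateau_timescales_masked(self):
        t = np.array([0.0, 0.1, 0.2, 0.3, 2.0, 2.1, 2.2, 2.3])
        TD = temporal_distances(t)
        rngl = np.random.default_rng(1)
        D = TD.values + 0.01 * rngl.uniform(size=TD.values.shape)
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        tcp = compute_tcp(D, TD, min_pairs=4)
        # between 0.75 d and 1.5 d no new pair enters: those grid points mask
        grid = tcp.timescales
        plateau = (grid >= 0.75) & (grid <= 1.5)
        assert not tcp.valid[plateau].any()

    def test_last_valid_reproduces_global_rho(self, linear_cohort):
        D = dissimilarity_matrix(linear_cohort.seizures)
        TD = temporal_distances(linear_cohort.times)
        tcp = compute_tcp(D, TD)
        res = mantel_spearman(D, TD, n_perm=10, seed=0)
        last = np.flatnonzero(tcp.valid)[-1]
        assert tcp.n_pairs[last] == len(D.upper_triangle())
        assert np.isclose(tcp.rho[last], res.rho)

    def test_empty_pattern_warns(self):
        t = np.array([0.0, 1.0, 2.0])
        TD = temporal_distances(t)
        D = TD.values.copy()
        with pytest.warns(UserWarning, match="no timescale"):
            tcp = compute_tcp(D, TD, min_pairs=7)
        assert not tcp.any_valid
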