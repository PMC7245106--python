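"""DTW seizure dissimilarity, band decomposition, projections, clustering."""

from functools import lru_cache

import numpy as np
import pytest

from szpath import (
    band_contributions,
    cluster_pathways,
    dissimilarity_matrix,
    dtw_l1,
    mds_project,
    seizure_dissimilarity,
)
from szpath.dissimilarity import DissimilarityMatrix, classical_mds
from szpath.synth import random_skeleton, synthesize_seizure_connectivity


def exhaustive_dtw(cost: np.ndarray):
    """Independent oracle: enumerate every admissible warping path.

    Returns (min total cost, list of (length, mean) over all optimal paths).
    Feasible for m, n <= 6 (Delannoy-number many paths).
    """
    m, n = cost.shape
    paths = []

    def walk(i, j, acc, steps):
        acc = acc + cost[i, j]
        steps = steps + 1
        if i == m - 1 and j == n - 1:
            paths.append((acc, steps))
            return
        if i + 1 < m:
            walk(i + 1, j, acc, steps)
        if j + 1 < n:
            walk(i, j + 1, acc, steps)
        if i + 1 < m and j + 1 < n:
            walk(i + 1, j + 1, acc, steps)

    walk(0, 0, 0.0, 0)
    best = min(p[0] for p in paths)
    optimal = [(k, c / k) for c, k in paths if c <= best + 1e-12]
    return best, optimal


class TestDtw:
    def test_identical_series_zero_cost_diagonal(self, small_skeleton):
        s = synthesize_seizure_connectivity(small_skeleton, 0.4, 0.0)
        path = dtw_l1(s, s)
        assert path.total_cost == 0.0
        assert np.array_equal(path.pairs[:, 0], path.pairs[:, 1])

    def test_duplicated_windows_cost_zero(self, rng):
        A = rng.uniform(size=(12, 5))  # features x windows
        B = np.repeat(A, 2, axis=1)
        assert seizure_dissimilarity(A, B) == 0.0

    def test_single_window_forced_path(self, rng):
        A = rng.uniform(size=(6, 1))
        B = rng.uniform(size=(6, 4))
        path = dtw_l1(A, B)
        assert np.array_equal(path.pairs[:, 0], np.zeros(4, dtype=int))
        expected = np.abs(A[:, 0, None] - B).sum(axis=0)
        assert np.allclose(path.step_dists, expected)

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="feature dimensions differ"):
            dtw_l1(rng.uniform(size=(6, 3)), rng.uniform(size=(7, 3)))

    @pytest.mark.parametrize("shape", [(3, 4), (5, 5), (6, 2), (4, 6)])
    def test_matches_exhaustive_oracle(self, rng, shape):
        mA, mB = shape
        A = rng.uniform(size=(8, mA))
        B = rng.uniform(size=(8, mB))
        path = dtw_l1(A, B)
        from scipy.spatial.distance import cdist

        best, optimal = exhaustive_dtw(cdist(A.T, B.T, "cityblock"))
        assert np.isclose(path.total_cost, best)
        diss = seizure_dissimilarity(A, B)
        assert any(np.isclose(diss, mean) for _, mean in optimal)


class TestDissimilarity:
    def test_constant_pathways_give_l1_distance(self, rng):
        u = rng.uniform(size=8)
        v = rng.uniform(size=8)
        A = np.tile(u[:, None], (1, 3))
        B = np.tile(v[:, None], (1, 7))
        assert np.isclose(seizure_dissimilarity(A, B), np.abs(u - v).sum())

    def test_disjoint_support_windows_hit_the_bound(self):
        # per-band-normalised single windows with disjoint supports: L1 = 2
        # per band, 12 over six bands
        u = np.zeros(12)
        v = np.zeros(12)
        u[::2] = 1.0  # six bands of two features each
        v[1::2] = 1.0
        assert np.isclose(seizure_dissimilarity(u[:, None], v[:, None]), 12.0)

    def test_speed_invariance(self, small_skeleton):
        s = synthesize_seizure_connectivity(small_skeleton, 0.7, 0.0)
        dilated = np.repeat(s.features, 3, axis=1)
        assert seizure_dissimilarity(s.features, dilated) == 0.0

    def test_matrix_of_identical_seizures_is_zero(self, small_skeleton):
        s = synthesize_seizure_connectivity(small_skeleton, 0.2, 0.0)
        D = dissimilarity_matrix([s, s, s])
        assert np.allclose(D.values, 0.0)

    def test_permutation_consistency(self, linear_cohort):
        szs = linear_cohort.seizures[:4]
        D = dissimilarity_matrix(szs).values
        perm = [2, 0, 3, 1]
        Dp = dissimilarity_matrix([szs[i] for i in perm]).values
        assert np.allclose(Dp, D[np.ix_(perm, perm)])

    def test_mixed_dimensions_rejected(self, rng):
        with pytest.raises(ValueError, match="mixed feature dimensions"):
            dissimilarity_matrix([rng.uniform(size=(6, 3)), rng.uniform(size=(8, 3))])


class TestBandContributions:
    def test_single_band_difference_isolated(self, rng):
        bbi = np.repeat(np.arange(6), 2)
        u = rng.uniform(size=12)
        v = u.copy()
        v[:2] += 0.5  # perturb only the delta block
        contrib = band_contributions(u[:, None], v[:, None], bbi)
        assert np.allclose(contrib[1:], 0.0)
        assert contrib[0] > 0

    def test_contributions_sum_to_dissimilarity(self, small_skeleton):
        a = synthesize_seizure_connectivity(small_skeleton, 0.1, 0.02, seed=1)
        b = synthesize_seizure_connectivity(small_skeleton, 0.9, 0.02, seed=2)
        contrib = band_contributions(a, b)
        assert np.all(contrib >= 0)
        assert np.isclose(contrib.sum(), seizure_dissimilarity(a, b), atol=1e-9)

    def test_identical_seizures_all_zero(self, small_skeleton):
        s = synthesize_seizure_connectivity(small_skeleton, 0.5, 0.0)
        assert np.allclose(band_contributions(s, s), 0.0)


class TestProjection:
    def test_line_embeds_exactly(self):
        # collinear points whose L1 distances are Euclidean-embeddable
        X = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        coords, stress = mds_project(X)
        assert stress < 1e-6

    def test_identical_points_collapse(self):
        coords, stress = mds_project(np.ones((5, 3)))
        assert stress == 0.0
        assert np.allclose(coords, coords[0])

    def test_rank_order_preserved(self, rng):
        # 50 points on a planar manifold in 10-D: a 2-D projection can
        # preserve the distance order
        plane = rng.uniform(size=(50, 2))
        X = plane @ rng.uniform(0.5, 1.5, size=(2, 10))
        coords, _ = mds_project(X, seed=0)
        from scipy.spatial.distance import pdist
        from scipy.stats import spearmanr

        r, _ = spearmanr(pdist(X, "cityblock"), pdist(coords))
        assert r > 0.9

    def test_deterministic_given_seed(self, rng):
        X = rng.uniform(size=(20, 6))
        c1, s1 = mds_project(X, seed=3)
        c2, s2 = mds_project(X, seed=3)
        assert np.array_equal(c1, c2) and s1 == s2

    def test_classical_mds_recovers_euclidean_config(self, rng):
        P = rng.standard_normal((10, 2))
        from scipy.spatial.distance import squareform, pdist

        D = squareform(pdist(P))
        emb = classical_mds(D, 2)
        D2 = squareform(pdist(emb))
        assert np.allclose(D, D2, atol=1e-8)


class TestClustering:
    def _planted_two_groups(self, seed=0):
        rng = np.random.default_rng(seed)
        n1, n2 = 6, 6
        centers = np.array([0.0, 10.0])
        pts = np.r_[centers[0] + rng.normal(0, 0.3, n1), centers[1] + rng.normal(0, 0.3, n2)]
        D = np.abs(pts[:, None] - pts[None, :])
        return D, np.r_[np.zeros(n1, int), np.ones(n2, int)]

    def test_planted_groups_recovered(self):
        D, truth = self._planted_two_groups()
        res = cluster_pathways(D, max_k=5, seed=0)
        assert res.k == 2
        # same partition up to label swap
        a = res.assignments
        assert len({(t, x) for t, x in zip(truth, a)}) == 2

    def test_unstructured_dissimilarities_read_as_spectrum(self):
        spectrum_votes = 0
        for seed in range(7):
            rng = np.random.default_rng(seed)
            pts = rng.uniform(size=(10, 2))
            D = np.abs(pts[:, None] - pts[None, :]).sum(-1)
            res = cluster_pathways(D, max_k=4, seed=seed)
            spectrum_votes += res.is_spectrum
        assert spectrum_votes >= 4

    def test_assignments_partition_all_seizures(self):
        D, _ = self._planted_two_groups(seed=3)
        res = cluster_pathways(D, max_k=4, seed=1)
        assert res.assignments.shape == (12,)
        assert np.all(res.assignments >= 1)

    def test_too_few_seizures_rejected(self):
        with pytest.raises(ValueError):
            cluster_pathways(np.zeros((2, 2)), max_k=2)


def test_triangle_inequality_can_fail():
    """The dissimilarity is not a metric distance.  Closed-form violation:
    duplicating B's last window is free (speed invariance), but it tilts the
    path-average against A, so Diss(A, C) > Diss(A, B) + Diss(B, C)."""
    A = np.array([[0.0]])
    B = np.array([[0.0, 8.0]])
    C = np.array([[0.0, 8.0, 8.0]])
    d_ab = seizure_dissimilarity(A, B)  # (0 + 8) / 2
    d_bc = seizure_dissimilarity(B, C)  # duplication: 0
    d_ac = seizure_dissimilarity(A, C)  # (0 + 8 + 8) / 3
    assert np.isclose(d_ab, 4.0) and d_bc == 0.0 and np.isclose(d_ac, 16 / 3)
    assert d_ac > d_ab + d_bc


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10**6))
def test_dissimilarity_symmetric_nonnegative_bounded(seed):
    """Property: Diss is symmetric, nonnegative, and never exceeds the
    largest pointwise window distance (it is a mean over aligned pairs)."""
    from scipy.spatial.distance import cdist

    rng = np.random.default_rng(seed)
    A = rng.uniform(size=(6, int(rng.integers(1, 7))))
    B = rng.uniform(size=(6, int(rng.integers(1, 7))))
    d_ab = seizure_dissimilarity(A, B)
    d_ba = seizure_dissimilarity(B, A)
    assert np.isclose(d_ab, d_ba)
    assert 0 <= d_ab <= cdist(A.T, B.T, "cityblock").max() + 1e-12
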