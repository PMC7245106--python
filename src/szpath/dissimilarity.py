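"""Seizure dissimilarity: DTW-aligned L1 distances between pathways.

Two seizures may traverse the same pathway through network space at
different rates, so their connectivity time courses are first aligned by
dynamic time warping (symmetric steps (1,0), (0,1), (1,1), unit weights,
fixed endpoints, no global band constraint) minimising the total L1
distance.  The dissimilarity of the pair is the mean L1 distance over the
warped path, so a seizure and any uniformly time-dilated copy of it are at
dissimilarity zero.  Note this is not a metric: the triangle inequality can
fail, and nothing downstream assumes it.

Also here: the per-band decomposition of a dissimilarity, Sammon-mapping
projection of windows for visualisation, and the spectrum-vs-clusters
summary (hierarchical clustering with gap-statistic model selection, where
k = 1 reads as "a spectrum of pathways").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import minimize
from scipy.spatial.distance import cdist, pdist, squareform

from .connectivity import ConnectivityTimeSeries

__all__ = [
    "WarpPath",
    "DissimilarityMatrix",
    "ClusterResult",
    "dtw_l1",
    "seizure_dissimilarity",
    "dissimilarity_matrix",
    "band_contributions",
    "classical_mds",
    "mds_project",
    "cluster_pathways",
]


# ---------------------------------------------------------------------------
# Dynamic time warping
# ---------------------------------------------------------------------------


@dataclass
class WarpPath:
    """An optimal alignment between two window sequences.

    pairs[k] = (a_k, b_k) are 0-based window indices, starting at (0, 0),
    ending at (m_A - 1, m_B - 1), each step advancing a, b, or both by one.
    step_dists[k] is the L1 distance of the aligned pair.
    """

    pairs: np.ndarray  # (K, 2) int
    step_dists: np.ndarray  # (K,)

    @property
    def total_cost(self) -> float:
        return float(self.step_dists.sum())

    @property
    def length(self) -> int:
        return self.pairs.shape[0]


def _as_windows(x) -> np.ndarray:
    """Coerce a ConnectivityTimeSeries or (features x m) array to (m, F)."""
    if isinstance(x, ConnectivityTimeSeries):
        return x.features.T
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return x[None, :]
    return x.T


def dtw_l1(A, B) -> WarpPath:
    """Optimal L1 warping path between two connectivity time courses.

    Accepts ConnectivityTimeSeries or (features x windows) arrays with the
    same feature dimension.
    """
    a, b = _as_windows(A), _as_windows(B)
    if a.shape[1] != b.shape[1]:
        raise ValueError(f"feature dimensions differ: {a.shape[1]} vs {b.shape[1]}")
    cost = cdist(a, b, metric="cityblock")
    m, n = cost.shape
    acc = np.full((m + 1, n + 1), np.inf)
    acc[0, 0] = 0.0
    for i in range(m):
        # accumulate row by row; vectorising the min over the three
        # predecessors keeps the inner loop in numpy
        acc[i + 1, 1:] = cost[i]
        prev = np.minimum(acc[i, 1:], acc[i, :-1])
        row = acc[i + 1]
        for j in range(n):
            row[j + 1] += min(prev[j], row[j])
    # backtrack
    i, j = m - 1, n - 1
    rpairs = [(i, j)]
    while i > 0 or j > 0:
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            k = int(np.argmin((acc[i, j], acc[i, j + 1], acc[i + 1, j])))
            if k == 0:
                i, j = i - 1, j - 1
            elif k == 1:
                i -= 1
            else:
                j -= 1
        rpairs.append((i, j))
    pairs = np.array(rpairs[::-1], dtype=int)
    return WarpPath(pairs=pairs, step_dists=cost[pairs[:, 0], pairs[:, 1]])


def seizure_dissimilarity(A, B) -> float:
    """Mean L1 distance over the optimal warping path (0 iff the two
    pathways coincide up to warping; at most 2 per band block)."""
    path = dtw_l1(A, B)
    return path.total_cost / path.length


# ---------------------------------------------------------------------------
# Matrices and decompositions
# ---------------------------------------------------------------------------


@dataclass
class DissimilarityMatrix:
    """Symmetric seizure-pair dissimilarities with zero diagonal."""

    values: np.ndarray
    seizure_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        S = self.values.shape[0]
        if self.values.shape != (S, S):
            raise ValueError("dissimilarity matrix must be square")
        if len(self.seizure_ids) != S:
            raise ValueError("seizure_ids length mismatch")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("dissimilarity matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.values < 0):
            raise ValueError("dissimilarities must be nonnegative")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


def dissimilarity_matrix(seizures) -> DissimilarityMatrix:
    """All pairwise seizure dissimilarities for one patient."""
    seizures = list(seizures)
    if len(seizures) < 2:
        raise ValueError("need at least 2 seizures")
    dims = {s.n_features if isinstance(s, ConnectivityTimeSeries) else np.asarray(s).shape[0]
            for s in seizures}
    if len(dims) != 1:
        raise ValueError(f"mixed feature dimensions {sorted(dims)}")
    S = len(seizures)
    D = np.zeros((S, S))
    for i in range(S):
        for j in range(i + 1, S):
            D[i, j] = D[j, i] = seizure_dissimilarity(seizures[i], seizures[j])
    ids = [
        s.seizure_id if isinstance(s, ConnectivityTimeSeries) and s.seizure_id else f"sz{i + 1:02d}"
        for i, s in enumerate(seizures)
    ]
    return DissimilarityMatrix(values=D, seizure_ids=ids)


def band_contributions(A, B, band_block_index: np.ndarray | None = None) -> np.ndarray:
    """Per-band mean warped L1 distances; sums to the pair's dissimilarity.

    The warp path is computed on the full feature vector and then the L1
    distance of each aligned pair is split by band block.
    """
    if band_block_index is None:
        if not isinstance(A, ConnectivityTimeSeries):
            raise ValueError("band_block_index required for plain arrays")
        band_block_index = A.band_block_index
    band_block_index = np.asarray(band_block_index, dtype=int)
    a, b = _as_windows(A), _as_windows(B)
    path = dtw_l1(A, B)
    diffs = np.abs(a[path.pairs[:, 0]] - b[path.pairs[:, 1]])  # (K, F)
    n_bands = int(band_block_index.max()) + 1
    contrib = np.array(
        [diffs[:, band_block_index == k].sum(axis=1).mean() for k in range(n_bands)]
    )
    return contrib


# ---------------------------------------------------------------------------
# Low-dimensional projections
# ---------------------------------------------------------------------------


def classical_mds(D: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Torgerson's classical MDS of a symmetric distance matrix.

    Double-centres -D^2/2 and embeds on the top nonnegative eigenvalues;
    components beyond the matrix's positive spectrum come out as zeros.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    Bmat = -0.5 * J @ (D**2) @ J
    w, v = np.linalg.eigh(Bmat)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    w = np.clip(w[:n_components], 0.0, None)
    return v[:, :n_components] * np.sqrt(w)


def mds_project(
    windows: np.ndarray,
    n_components: int = 2,
    seed: int = 0,
    max_iter: int = 500,
) -> tuple[np.ndarray, float]:
    """Sammon mapping of window vectors from their pairwise L1 distances.

    Minimises the Sammon stress sum((d - dhat)^2 / d) / sum(d) with scipy's
    L-BFGS from a classical-MDS initialisation (jittered by the seed), so
    small input distances are preserved preferentially.  Duplicate points
    (zero input distance) are excluded from the stress rather than dividing
    by zero.  Returns (coordinates, stress).
    """
    X = np.asarray(windows, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need at least 3 window vectors")
    d = pdist(X, metric="cityblock")
    pos = d > 1e-12
    if not pos.any():  # all points identical
        return np.zeros((X.shape[0], n_components)), 0.0
    scale = d[pos].sum()
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    init = classical_mds(squareform(d), n_components)
    init = init + 1e-6 * rng.standard_normal(init.shape)

    def stress_grad(flat: np.ndarray):
        Y = flat.reshape(n, n_components)
        dhat = pdist(Y)
        dhat_safe = np.maximum(dhat, 1e-12)
        diff = np.where(pos, dhat - d, 0.0)
        stress = (diff**2 / np.where(pos, d, 1.0))[pos].sum() / scale
        coef = np.where(pos, 2.0 * diff / (np.where(pos, d, 1.0) * dhat_safe), 0.0) / scale
        C = squareform(coef)
        G = (C.sum(axis=1)[:, None] * Y) - C @ Y
        return stress, G.ravel()

    res = minimize(
        stress_grad, init.ravel(), jac=True, method="L-BFGS-B", options={"maxiter": max_iter}
    )
    return res.x.reshape(n, n_components), float(res.fun)


# ---------------------------------------------------------------------------
# Spectrum vs. clusters
# ---------------------------------------------------------------------------


@dataclass
class ClusterResult:
    k: int
    assignments: np.ndarray
    gap: np.ndarray  # gap statistic per k = 1..max_k
    se: np.ndarray  # reference standard errors
    is_spectrum: bool  # k == 1: a spectrum of pathways, not distinct groups


def _within_dispersion(points: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for c in np.unique(labels):
        P = points[labels == c]
        if len(P) > 1:
            total += (pdist(P) ** 2).sum() / (2 * len(P))
    return total


def _hier_labels(points: np.ndarray, k: int) -> np.ndarray:
    if k == 1:
        return np.ones(len(points), dtype=int)
    Z = linkage(points, method="ward")
    return fcluster(Z, t=k, criterion="maxclust")


def cluster_pathways(
    D: DissimilarityMatrix | np.ndarray,
    max_k: int = 5,
    n_ref: int = 100,
    seed: int = 0,
) -> ClusterResult:
    """Are a patient's pathways distinct groups or a spectrum?

    Embeds the dissimilarity matrix by classical MDS, clusters the embedding
    hierarchically (Ward linkage), and picks the number of clusters by the
    gap statistic against ``n_ref`` uniform-box reference sets with the
    one-standard-error rule; k = 1 is allowed and reported as a spectrum.
    """
    values = D.values if isinstance(D, DissimilarityMatrix) else np.asarray(D, dtype=float)
    S = values.shape[0]
    if S < 3:
        raise ValueError("need at least 3 seizures to assess clustering")
    max_k = min(max_k, S - 1)
    emb = classical_mds(values, n_components=min(S - 1, 4))
    # drop identically-zero embedding dimensions
    emb = emb[:, np.ptp(emb, axis=0) > 0] if np.any(np.ptp(emb, axis=0) > 0) else emb[:, :1]
    rng = np.random.default_rng(seed)
    lo, hi = emb.min(axis=0), emb.max(axis=0)

    ks = np.arange(1, max_k + 1)
    log_w = np.array([np.log(max(_within_dispersion(emb, _hier_labels(emb, k)), 1e-300)) for k in ks])
    ref_log_w = np.empty((n_ref, len(ks)))
    for b in range(n_ref):
        ref = rng.uniform(lo, hi, size=emb.shape)
        ref_log_w[b] = [
            np.log(max(_within_dispersion(ref, _hier_labels(ref, k)), 1e-300)) for k in ks
        ]
    gap = ref_log_w.mean(axis=0) - log_w
    se = ref_log_w.std(axis=0, ddof=0) * np.sqrt(1 + 1 / n_ref)

    k_chosen = int(ks[-1])
    for idx in range(len(ks) - 1):
        if gap[idx] >= gap[idx + 1] - se[idx + 1]:
            k_chosen = int(ks[idx])
            break
    labels = _hier_labels(emb, k_chosen)
    return ClusterResult(
        k=k_chosen, assignments=labels, gap=gap, se=se, is_spectrum=(k_chosen == 1)
    )
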