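"""Low-rank nonnegative denoising of the cohort connectivity matrix.

Small window-to-window fluctuations in coherence would put a high noise
floor under every seizure comparison.  The cohort matrix V (features x
windows, all seizures concatenated) is therefore approximated as V ~ W x H
with nonnegative basis patterns W and coefficients H, the rank r chosen by
stability across seeded re-fits, and the reconstruction V* = W x H
renormalised per band block so that reconstruction accuracy cannot leak
into downstream distances.

The renormalisation is applied per band block (each of the six blocks of a
window sums to one) rather than to the whole vector: with per-band
normalisation the maximum L1 distance between two windows is 2 per band
(12 over six bands), which is what makes observed seizure dissimilarities
above 2 possible at all.  A ``mode="vector"`` switch provides whole-vector
normalisation for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import NMF
from sklearn.exceptions import ConvergenceWarning

__all__ = [
    "NMFModel",
    "RankSelection",
    "factorize",
    "select_rank_stability",
    "denoise_reconstruct",
    "load_factorization",
]


@dataclass
class NMFModel:
    """One fitted factorization V ~ W x H."""

    W: np.ndarray  # features x r, nonnegative basis patterns
    H: np.ndarray  # r x windows, nonnegative coefficients
    rank: int
    seed: int
    fit_error: float  # relative Frobenius residual ||V - WH||_F / ||V||_F
    converged: bool = True
    n_iter: int = 0

    def __post_init__(self) -> None:
        if np.any(self.W < 0) or np.any(self.H < 0):
            raise ValueError("W and H must be nonnegative")
        if not 0 <= self.fit_error <= 1 + 1e-9:
            raise ValueError("fit_error must lie in [0, 1]")


@dataclass
class RankSelection:
    rank: int
    scores: dict[int, float]  # rank -> mean cross-run basis stability
    warning: str | None = None


def factorize(
    V: np.ndarray,
    rank: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> NMFModel:
    """Fit a rank-``rank`` NMF to the nonnegative matrix V.

    Minimises the Frobenius residual by coordinate descent from a seeded
    random initialisation; non-convergence within ``max_iter`` is reported
    on the returned model (``converged=False``), never silently.
    """
    V = np.asarray(V, dtype=float)
    if np.any(V < 0):
        raise ValueError("V must be nonnegative")
    if not 1 <= rank < min(V.shape):
        raise ValueError(f"rank must lie in [1, {min(V.shape) - 1}]")
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        model = NMF(
            n_components=rank,
            init="random",
            solver="cd",
            beta_loss="frobenius",
            max_iter=max_iter,
            tol=tol,
            random_state=seed,
        )
        try:
            Wm = model.fit_transform(V)
        except ConvergenceWarning:
            converged = False
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                model = NMF(
                    n_components=rank,
                    init="random",
                    solver="cd",
                    beta_loss="frobenius",
                    max_iter=max_iter,
                    tol=tol,
                    random_state=seed,
                )
                Wm = model.fit_transform(V)
    H = model.components_
    denom = np.linalg.norm(V)
    err = float(np.linalg.norm(V - Wm @ H) / denom) if denom > 0 else 0.0
    return NMFModel(
        W=Wm, H=H, rank=rank, seed=seed, fit_error=min(err, 1.0),
        converged=converged, n_iter=model.n_iter_,
    )


def _greedy_match_similarity(Wa: np.ndarray, Wb: np.ndarray) -> float:
    """Mean cosine similarity of greedily matched basis columns."""
    na = Wa / np.maximum(np.linalg.norm(Wa, axis=0, keepdims=True), 1e-12)
    nb = Wb / np.maximum(np.linalg.norm(Wb, axis=0, keepdims=True), 1e-12)
    sim = na.T @ nb
    r = sim.shape[0]
    total = 0.0
    rows = list(range(r))
    cols = list(range(r))
    for _ in range(r):
        sub = sim[np.ix_(rows, cols)]
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        total += sub[i, j]
        del rows[i], cols[j]
    return total / r


def select_rank_stability(
    V: np.ndarray,
    rank_range: range | list[int],
    n_runs: int = 20,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-9,
    spread_tol: float = 1e-3,
    stability_margin: float = 0.005,
) -> RankSelection:
    """Choose the factorization rank by cross-run basis stability.

    For each candidate rank, ``n_runs`` seeded factorizations are fit from
    different random initialisations; basis vectors are matched across every
    run pair by greedy maximum cosine similarity and the rank's score is the
    mean matched similarity.  Ranks *below* the true one are often just as
    stable as the true rank (the merged solution can be unique), so among
    ranks within ``stability_margin`` of the best score the largest is
    selected: the richest decomposition that is still fully reproducible.
    Tight convergence (``tol``) matters here — half-converged fits differ
    across runs for reasons that have nothing to do with the rank.

    If the scores are indistinguishable across all ranks (spread below
    ``spread_tol``), the smallest rank is returned with a warning.
    """
    V = np.asarray(V, dtype=float)
    ranks = sorted(set(int(r) for r in rank_range))
    if not ranks:
        raise ValueError("empty rank range")
    if ranks[0] < 2 or ranks[-1] >= min(V.shape):
        raise ValueError("rank_range must lie within [2, min(V.shape) - 1]")
    if n_runs < 2:
        raise ValueError("stability is undefined for fewer than 2 runs")
    root = np.random.SeedSequence(seed)
    run_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(n_runs)]
    scores: dict[int, float] = {}
    for r in ranks:
        Ws = [factorize(V, r, seed=s, max_iter=max_iter, tol=tol).W for s in run_seeds]
        pair_scores = [
            _greedy_match_similarity(Ws[i], Ws[j])
            for i in range(n_runs)
            for j in range(i + 1, n_runs)
        ]
        scores[r] = float(np.mean(pair_scores))
    values = np.array([scores[r] for r in ranks])
    if values.max() - values.min() < spread_tol:
        return RankSelection(
            rank=ranks[0],
            scores=scores,
            warning="stability scores indistinguishable across ranks; "
            "returning the smallest rank",
        )
    candidates = [r for r, v in zip(ranks, values) if v >= values.max() - stability_margin]
    return RankSelection(rank=max(candidates), scores=scores)


def denoise_reconstruct(
    model: NMFModel,
    band_block_index: np.ndarray,
    mode: str = "band",
) -> np.ndarray:
    """Reconstruct V* = W x H and renormalise each window.

    ``mode="band"`` (default) rescales every band block of every window to
    sum to one; ``mode="vector"`` rescales whole windows instead.  An
    all-zero reconstructed block is an error naming the window and band.
    """
    band_block_index = np.asarray(band_block_index, dtype=int)
    if band_block_index.shape[0] != model.W.shape[0]:
        raise ValueError("band_block_index length does not match the model's feature count")
    V_star = model.W @ model.H
    if mode == "vector":
        sums = V_star.sum(axis=0)
        bad = np.flatnonzero(sums <= 0)
        if bad.size:
            raise ValueError(f"window {bad[0]}: all-zero reconstruction")
        return V_star / sums
    if mode != "band":
        raise ValueError("mode must be 'band' or 'vector'")
    for b in np.unique(band_block_index):
        sel = band_block_index == b
        sums = V_star[sel].sum(axis=0)
        bad = np.flatnonzero(sums <= 0)
        if bad.size:
            raise ValueError(f"window {bad[0]}, band {b}: all-zero reconstructed block")
        V_star[sel] /= sums
    return V_star


def load_factorization(path, w_key: str = "W", h_key: str = "H"):
    """Load a deposited factorization (W, H) from an HDF5 container.

    Reads plain HDF5 and MATLAB v7.3 files (both are HDF5); matrices stored
    by MATLAB are transposed back to features x r and r x windows with the
    convention that W has more rows than columns.
    """
    import h5py

    with h5py.File(path, "r") as f:
        W = np.asarray(f[w_key], dtype=float)
        H = np.asarray(f[h_key], dtype=float)
    if W.shape[0] < W.shape[1]:  # MATLAB v7.3 stores arrays transposed
        W = W.T
    if W.shape[1] != H.shape[0]:
        if W.shape[1] == H.shape[1]:
            H = H.T
        else:
            raise ValueError(f"incompatible factor shapes {W.shape} x {H.shape}")
    return NMFModel(W=W, H=H, rank=W.shape[1], seed=-1, fit_error=0.0)
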