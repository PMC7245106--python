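"""Temporal structure of seizure dissimilarities.

Seizure pairs that occur closer together in time tend to have more similar
pathways.  This module quantifies that: temporal distance matrices |t_i -
t_j| in days, the one-tailed Mantel permutation test of the Spearman
correlation between dissimilarities and temporal distances, BH-FDR across
patients, and the timescale scan (temporal correlation pattern, TCP) that
restricts the correlation to pairs within a timescale T.

The Mantel permutation applies one random relabelling simultaneously to the
rows and columns of one matrix, so the permutation distribution respects
the dependence structure of distance matrices.  The p-value is the literal
proportion of permuted correlations >= the observed one; a smoothed
(b + 1)/(n + 1) estimator is available as a switch, and for S <= 7 all S!
relabellings can be enumerated exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .dissimilarity import DissimilarityMatrix

__all__ = [
    "TemporalDistanceMatrix",
    "MantelResult",
    "TemporalCorrelationPattern",
    "temporal_distances",
    "mantel_spearman",
    "bh_fdr",
    "compute_tcp",
]


@dataclass
class TemporalDistanceMatrix:
    """|t_i - t_j| in days for all seizure pairs."""

    values: np.ndarray
    times: np.ndarray
    has_duplicates: bool = False

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


def temporal_distances(times: np.ndarray, units: str = "days") -> TemporalDistanceMatrix:
    """Pairwise elapsed time between seizure onsets.

    ``times`` must be sorted fractional days with the first seizure at 0
    (pass ``units="days"`` explicitly if calling with raw numbers from
    another source).  Duplicate onset times are allowed (distance 0) but
    flagged on the result.
    """
    if units != "days":
        raise ValueError(f"onset times must be supplied in days, got units={units!r}")
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("need at least 2 onset times")
    if t[0] != 0:
        raise ValueError("times must be relative to the first seizure (times[0] == 0)")
    if np.any(np.diff(t) < 0):
        raise ValueError("times must be sorted")
    dup = bool(np.any(np.diff(t) == 0))
    if dup:
        warnings.warn("duplicate onset times (temporal distance 0)", stacklevel=2)
    return TemporalDistanceMatrix(
        values=np.abs(t[:, None] - t[None, :]), times=t, has_duplicates=dup
    )


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------


@dataclass
class MantelResult:
    rho: float
    p: float
    n_perm: int
    tail: str = "greater"
    mode: str = "sampled"
    valid: bool = True  # False when a matrix's upper triangle is constant


def _utri_spearman_setup(x: np.ndarray):
    """Precompute the pieces of a Spearman correlation against permuted
    copies of a rank matrix: since a joint row/column permutation only
    shuffles the upper-triangle multiset, ranks (and hence means and
    variances) are permutation-invariant and only the cross term changes."""
    r = rankdata(x)
    rc = r - r.mean()
    denom = np.sqrt((rc**2).sum())
    return rc, denom


def _rank_matrix(M: np.ndarray) -> np.ndarray:
    n = M.shape[0]
    iu = np.triu_indices(n, k=1)
    R = np.zeros_like(M, dtype=float)
    R[iu] = rankdata(M[iu])
    return R + R.T


def mantel_spearman(
    D: DissimilarityMatrix | np.ndarray,
    TD: TemporalDistanceMatrix | np.ndarray,
    n_perm: int = 10000,
    seed: int = 0,
    mode: str = "sampled",
    smoothed: bool = False,
) -> MantelResult:
    """One-tailed Mantel test of Spearman's rho between two distance
    matrices.

    rho is the Spearman correlation (average ranks on ties) of the two
    upper-triangle vectors.  Significance comes from jointly permuting the
    rows and columns of the dissimilarity matrix: ``mode="sampled"`` draws
    ``n_perm`` random relabellings, ``mode="exhaustive"`` enumerates all S!
    relabellings (S <= 7).  p is the proportion of permuted rho >= observed
    (with ``smoothed=True``, the (b + 1)/(n + 1) variant).

    A constant upper triangle makes rho undefined; the result is returned
    flagged ``valid=False`` (and should be excluded from FDR correction).
    """
    Dv = D.values if isinstance(D, DissimilarityMatrix) else np.asarray(D, dtype=float)
    Tv = TD.values if isinstance(TD, TemporalDistanceMatrix) else np.asarray(TD, dtype=float)
    if Dv.shape != Tv.shape:
        raise ValueError("matrices must have identical shape")
    S = Dv.shape[0]
    if S < 4:
        raise ValueError("need at least 4 seizures for a meaningful Mantel test")
    iu = np.triu_indices(S, k=1)
    x, y = Tv[iu], Dv[iu]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return MantelResult(rho=np.nan, p=np.nan, n_perm=0, mode=mode, valid=False)

    xc, xden = _utri_spearman_setup(x)
    yc, yden = _utri_spearman_setup(y)
    # same float path as the TCP scan, so rho(T_max) == Mantel rho exactly
    rho_obs = _spearman(x, y)

    RD = _rank_matrix(Dv)  # permutation-invariant rank multiset
    x_full = np.zeros((S, S))
    x_full[iu] = xc
    xc_mat = x_full + x_full.T

    if mode == "exhaustive":
        if S > 7:
            raise ValueError("exhaustive mode supports at most 7 seizures (S! relabellings)")
        perms = np.array(list(permutations(range(S))))
    elif mode == "sampled":
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(S) for _ in range(n_perm)])
    else:
        raise ValueError("mode must be 'sampled' or 'exhaustive'")

    # gather RD under each relabelling and correlate with the fixed TD ranks
    RP = RD[perms[:, :, None], perms[:, None, :]]  # (n_perm, S, S)
    perm_rho = (RP[:, iu[0], iu[1]] - RD[iu].mean()) @ xc / (xden * yden)
    b = int(np.sum(perm_rho >= rho_obs - 1e-12))
    n = len(perms)
    p = (b + 1) / (n + 1) if smoothed else b / n
    return MantelResult(rho=rho_obs, p=float(p), n_perm=n, mode=mode)


def bh_fdr(pvalues, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment across patients.

    NaN entries (patients whose correlation was undefined) are excluded
    from the correction and stay NaN/False in the output.  Returns
    (adjusted p-values, significance flags at ``alpha``).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to correct")
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    adj = np.full(p.shape, np.nan)
    flags = np.zeros(p.shape, dtype=bool)
    if ok.any():
        rej, adj_ok, *_ = multipletests(p[ok], alpha=alpha, method="fdr_bh")
        adj[ok] = adj_ok
        flags[ok] = adj_ok < alpha
    return adj, flags


# ---------------------------------------------------------------------------
# Temporal correlation patterns
# ---------------------------------------------------------------------------


@dataclass
class TemporalCorrelationPattern:
    """Spearman rho between dissimilarities and temporal distances as a
    function of timescale T (pairs with TD <= T only).

    Timescales with fewer than the minimum pair count, or where no new pair
    entered since the previous grid point, are masked invalid.  The last
    valid timescale includes every pair, so its rho equals the global
    Mantel correlation.
    """

    timescales: np.ndarray
    rho: np.ndarray  # NaN where invalid
    n_pairs: np.ndarray
    valid: np.ndarray
    warning: str | None = None

    @property
    def any_valid(self) -> bool:
        return bool(self.valid.any())


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    rx, ry = rankdata(x), rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    den = np.sqrt((rx**2).sum() * (ry**2).sum())
    if den == 0:
        return np.nan
    return float((rx * ry).sum() / den)


def tcp_grid(max_td: float, step: float = 0.25) -> np.ndarray:
    """Timescale grid from ``step`` up to (and covering) the largest
    temporal distance."""
    n = int(np.ceil(max_td / step - 1e-9))
    return step * np.arange(1, max(n, 1) + 1)


def compute_tcp(
    D: DissimilarityMatrix | np.ndarray,
    TD: TemporalDistanceMatrix | np.ndarray,
    step: float = 0.25,
    min_pairs: int = 7,
) -> TemporalCorrelationPattern:
    """Scan the dissimilarity/temporal-distance correlation over timescales.

    For each T on a ``step``-day grid up to the patient's largest temporal
    distance, Spearman's rho is computed over seizure pairs with TD <= T.
    A timescale is masked if fewer than ``min_pairs`` pairs fall within it,
    if no new pair was added relative to the previous grid point, or if
    either restricted vector is constant.
    """
    Dv = D.values if isinstance(D, DissimilarityMatrix) else np.asarray(D, dtype=float)
    Tv = TD.values if isinstance(TD, TemporalDistanceMatrix) else np.asarray(TD, dtype=float)
    if Dv.shape != Tv.shape:
        raise ValueError("matrices must have identical shape")
    S = Dv.shape[0]
    iu = np.triu_indices(S, k=1)
    x, y = Tv[iu], Dv[iu]
    grid = tcp_grid(x.max(), step)
    rho = np.full(grid.shape, np.nan)
    n_pairs = np.zeros(grid.shape, dtype=int)
    valid = np.zeros(grid.shape, dtype=bool)
    prev_count = 0
    for k, T in enumerate(grid):
        sel = x <= T + 1e-12
        n_pairs[k] = sel.sum()
        new_pairs = n_pairs[k] > prev_count
        prev_count = n_pairs[k]
        if n_pairs[k] < min_pairs or not new_pairs:
            continue
        r = _spearman(x[sel], y[sel])
        if np.isnan(r):
            continue
        rho[k] = r
        valid[k] = True
    warning = None if valid.any() else (
        f"no timescale reaches {min_pairs} seizure pairs; pattern is empty"
    )
    if warning:
        warnings.warn(warning, stacklevel=2)
    return TemporalCorrelationPattern(
        timescales=grid, rho=rho, n_pairs=n_pairs, valid=valid, warning=warning
    )
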