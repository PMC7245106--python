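"""Synthetic seizure cohorts with planted pathway-drift structure.

Real monitoring data are a handful of days of irregularly timed seizures
whose network evolutions drift between recurrences.  This module emulates
exactly the pieces the downstream statistics consume, with known ground
truth:

* irregular onset times over a multi-day monitoring window;
* a per-seizure latent drift g(t) = l*t/7 + c*sin(2*pi*t) + n*eps, i.e. a
  linear trend with slope one per week, a 1-day sinusoid, and unit Gaussian
  noise, weighted by nonnegative (l, c, n);
* connectivity time courses that move along a "pathway spectrum" between two
  endpoint pathways A and B at mix lambda, the affine min-max squash of the
  drift to [0, 1] (monotone, and rank-exact for pairwise differences);
* optionally, raw multichannel signals with a shared band-limited source,
  for end-to-end exercise of the coherence estimator.

All generated feature vectors satisfy the same invariants as the real
pipeline (nonnegative, per-band block sums of one), so synthetic cohorts are
drop-in substitutes for real ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .connectivity import ConnectivityTimeSeries, _band_edge_indices

__all__ = [
    "CohortSpec",
    "PathwaySkeleton",
    "SyntheticCohort",
    "sample_seizure_times",
    "latent_drift",
    "random_skeleton",
    "synthesize_seizure_connectivity",
    "synthesize_ieeg",
    "generate_cohort",
]


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic patient.

    Defaults mirror a typical presurgical monitoring cohort: ~16 seizures
    over ~10 days (recordings in such cohorts span roughly 2-16 days),
    six frequency bands, and seizures lasting 10-20 connectivity windows.
    drift_params = (l_true, c_true, n_true) are the weights of the linear,
    circadian, and noise components of the planted pathway drift.
    """

    n_seizures: int = 16
    monitoring_days: float = 10.0
    n_channels: int = 8
    n_bands: int = 6
    windows_per_seizure: tuple[int, int] = (10, 20)
    drift_params: tuple[float, float, float] = (1.0, 0.0, 0.1)
    min_gap_days: float = 0.05
    within_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_seizures < 2:
            raise ValueError("need at least 2 seizures")
        if self.monitoring_days <= 0:
            raise ValueError("monitoring_days must be positive")
        if self.windows_per_seizure[0] < 2:
            raise ValueError("seizures must span at least 2 windows")
        if any(w < 0 for w in self.drift_params):
            raise ValueError("drift weights must be nonnegative")


@dataclass
class PathwaySkeleton:
    """Two endpoint pathways A and B in connectivity feature space.

    Each is an (n_windows, n_features) sequence of per-window feature
    vectors, nonnegative with every band block summing to one.  A seizure's
    pathway is a convex mix of the two, so the cohort forms a spectrum of
    pathways between them.
    """

    A: np.ndarray
    B: np.ndarray
    band_block_index: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.band_block_index = np.asarray(self.band_block_index, dtype=int)
        if self.A.shape != self.B.shape:
            raise ValueError("endpoint pathways must have identical shape")
        if self.A.shape[1] != self.band_block_index.shape[0]:
            raise ValueError("band_block_index length mismatch")
        for M in (self.A, self.B):
            if np.any(M < 0):
                raise ValueError("endpoint pathways must be nonnegative")
            for b in np.unique(self.band_block_index):
                s = M[:, self.band_block_index == b].sum(axis=1)
                if not np.allclose(s, 1.0, atol=1e-9):
                    raise ValueError(f"band block {b} of an endpoint does not sum to 1")

    @property
    def n_windows(self) -> int:
        return self.A.shape[0]


@dataclass
class SyntheticCohort:
    """One generated patient with full ground truth attached."""

    spec: CohortSpec
    times: np.ndarray  # onset times, fractional days since first seizure
    latent: np.ndarray  # g(t_i)
    lambdas: np.ndarray  # min-max squash of g: the planted pathway mix
    seizures: list[ConnectivityTimeSeries]
    skeleton: PathwaySkeleton


# ---------------------------------------------------------------------------
# Onset times and drift
# ---------------------------------------------------------------------------


def sample_seizure_times(
    n_seizures: int,
    monitoring_days: float,
    min_gap_days: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Irregular onset times over the monitoring window.

    Times are uniform on the window conditional on every consecutive gap
    being at least ``min_gap_days`` (drawn by the standard spacing
    transform), then shifted so the first seizure is at time 0.  Returned in
    fractional days, strictly increasing.
    """
    if n_seizures < 2:
        raise ValueError("need at least 2 seizures")
    if min_gap_days < 0:
        raise ValueError("min_gap_days must be nonnegative")
    slack = monitoring_days - (n_seizures - 1) * min_gap_days
    if slack <= 0 or n_seizures * min_gap_days > monitoring_days:
        raise ValueError(
            f"cannot place {n_seizures} seizures with gaps >= {min_gap_days} d "
            f"in {monitoring_days} d"
        )
    rng = np.random.default_rng(seed)
    u = np.sort(rng.uniform(0.0, slack, size=n_seizures))
    times = u + np.arange(n_seizures) * min_gap_days
    times -= times[0]
    return times


def latent_drift(
    times: np.ndarray,
    l_true: float,
    c_true: float,
    n_true: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Planted per-seizure drift g(t) = l*t/7 + c*sin(2*pi*t) + n*eps.

    The linear term has slope one per week, the sinusoid a period of one
    day, and eps ~ N(0, 1) independently per seizure.
    """
    if min(l_true, c_true, n_true) < 0:
        raise ValueError("drift weights must be nonnegative")
    t = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal(t.shape)
    return l_true * t / 7.0 + c_true * np.sin(2 * np.pi * t) + n_true * eps


# ---------------------------------------------------------------------------
# Connectivity synthesis
# ---------------------------------------------------------------------------


def random_skeleton(
    n_windows: int,
    n_channels: int,
    n_bands: int = 6,
    seed: int | np.random.Generator = 0,
    band_gap: float = 0.3,
) -> PathwaySkeleton:
    """Random endpoint pathways separated by a constant per-window L1 gap.

    Pathway A has per-band Dirichlet(1) anchor windows; B moves a fixed
    amount of mass between two edges of every band of every anchor, so
    ``||A_k - B_k||_1`` equals ``n_bands * band_gap`` for every anchor k.
    The constant gap makes the downstream dissimilarity of two seizures at
    mixes lambda_1, lambda_2 exactly proportional to |lambda_1 - lambda_2|
    regardless of how the warp distributes path steps, which is what lets
    planted drift translate into exact rank structure.
    """
    rng = np.random.default_rng(seed)
    n_edges = n_channels * (n_channels - 1) // 2
    if n_edges < 2:
        raise ValueError("need at least 2 edges per band to construct the gap")
    band_block_index, _ = _band_edge_indices(n_channels, n_bands)
    blocks = [rng.dirichlet(np.ones(n_edges), size=n_windows) for _ in range(n_bands)]
    A = np.concatenate(blocks, axis=1)
    # largest transferable mass that keeps B nonnegative at every anchor
    eps = band_gap / 2.0
    max_edge = min(b.max(axis=1).min() for b in blocks)
    eps = min(eps, 0.9 * max_edge)
    B = A.copy()
    for b, block in enumerate(blocks):
        sel = np.flatnonzero(band_block_index == b)
        hi = sel[np.argmax(block, axis=1)]
        lo = sel[np.argmin(block, axis=1)]
        rows = np.arange(n_windows)
        B[rows, hi] -= eps
        B[rows, lo] += eps
    return PathwaySkeleton(A=A, B=B, band_block_index=band_block_index)


def synthesize_seizure_connectivity(
    skeleton: PathwaySkeleton,
    mix_lambda: float,
    within_noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    n_windows: int | None = None,
    seizure_id: str = "",
) -> ConnectivityTimeSeries:
    """One seizure's connectivity time course at pathway mix ``mix_lambda``.

    Window k is renormalize((1 - lambda) * A_k + lambda * B_k + |noise|);
    noise is folded (absolute value) before the per-band renormalisation to
    preserve nonnegativity.  lambda = 0 with zero noise reproduces A.

    ``n_windows`` sets the seizure's duration: the seizure traverses the
    whole skeleton pathway at its own rate (anchor windows are resampled,
    repeating anchors when the seizure is longer than the skeleton), so
    duration differences are pure time dilations that DTW absorbs.
    """
    if not 0.0 <= mix_lambda <= 1.0:
        raise ValueError("mix_lambda must lie in [0, 1]")
    m = skeleton.n_windows if n_windows is None else int(n_windows)
    if m < 2:
        raise ValueError("a seizure needs at least 2 windows")
    rng = np.random.default_rng(seed)
    anchors = (np.arange(m) * skeleton.n_windows) // m  # monotone full traversal
    M = (1.0 - mix_lambda) * skeleton.A[anchors] + mix_lambda * skeleton.B[anchors]
    if within_noise_sd > 0:
        M = M + np.abs(rng.standard_normal(M.shape) * within_noise_sd)
    bbi = skeleton.band_block_index
    out = np.empty_like(M)
    for b in np.unique(bbi):
        sel = bbi == b
        s = M[:, sel].sum(axis=1, keepdims=True)
        if np.any(s <= 0):
            raise ValueError(f"band block {b} sums to zero after mixing")
        out[:, sel] = M[:, sel] / s
    n_ch = int(round((1 + np.sqrt(1 + 8 * (bbi == 0).sum())) / 2))
    _, edge_index = _band_edge_indices(n_ch, int(bbi.max()) + 1)
    return ConnectivityTimeSeries(
        features=out.T,
        band_block_index=bbi,
        window_start_times=np.arange(m, dtype=float),
        edge_index=edge_index,
        seizure_id=seizure_id,
    )


# ---------------------------------------------------------------------------
# Raw signal synthesis
# ---------------------------------------------------------------------------


def synthesize_ieeg(
    n_channels: int,
    fs: float,
    duration_s: float,
    shared_band: tuple[float, float] = (8.0, 13.0),
    snr: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Multichannel signal: one shared band-limited source plus independent
    white noise per channel.

    ``snr`` is the source-to-noise power ratio *within the shared band*
    (white noise spreads its power over the whole Nyquist range), so the
    analytic pairwise band coherence is (snr / (1 + snr))^2 — 0.25 at
    snr = 1, and 1 as snr -> inf (pass ``np.inf`` for a noise-free source).
    Returns an (n_channels, fs*duration_s) array.
    """
    f1, f2 = shared_band
    if not 0 < f1 < f2:
        raise ValueError("shared_band must satisfy 0 < f1 < f2")
    if fs < 2 * f2:
        raise ValueError(f"fs={fs} Hz cannot carry a source band up to {f2} Hz")
    if not snr > 0:
        raise ValueError("snr must be positive")
    rng = np.random.default_rng(seed)
    n_t = int(round(fs * duration_s))
    sos = signal.butter(4, [f1, f2], btype="bandpass", fs=fs, output="sos")
    source = signal.sosfiltfilt(sos, rng.standard_normal(n_t))
    source /= source.std()
    if np.isinf(snr):
        noise_sd = 0.0
    else:
        # white noise with in-band power 1/snr has total power scaled by the
        # ratio of the full Nyquist range to the band width
        noise_sd = np.sqrt((fs / 2) / ((f2 - f1) * snr))
    x = source[None, :] + noise_sd * rng.standard_normal((n_channels, n_t))
    return x


# ---------------------------------------------------------------------------
# Whole-cohort generation
# ---------------------------------------------------------------------------


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate one synthetic patient: onset times, planted drift, and one
    connectivity time course per seizure.

    Bit-reproducible: the same CohortSpec yields identical outputs.
    """
    root = np.random.SeedSequence(spec.seed)
    s_times, s_drift, s_skel, s_dur, s_noise = root.spawn(5)
    times = sample_seizure_times(
        spec.n_seizures, spec.monitoring_days, spec.min_gap_days, np.random.default_rng(s_times)
    )
    l_true, c_true, n_true = spec.drift_params
    g = latent_drift(times, l_true, c_true, n_true, np.random.default_rng(s_drift))
    # affine min-max squash to [0, 1]: monotone like a logistic, but it also
    # preserves the *ranks of pairwise differences* of g, so the planted
    # drift survives exactly into downstream dissimilarity ranks
    span = np.ptp(g)
    lambdas = np.full_like(g, 0.5) if span == 0 else (g - g.min()) / span
    w_lo, w_hi = spec.windows_per_seizure
    # skeleton length = shortest seizure, so every seizure covers the whole
    # pathway and duration differences are pure dilations
    skeleton = random_skeleton(w_lo, spec.n_channels, spec.n_bands, np.random.default_rng(s_skel))
    rng_dur = np.random.default_rng(s_dur)
    durations = rng_dur.integers(w_lo, w_hi + 1, size=spec.n_seizures)
    noise_rng = np.random.default_rng(s_noise)
    seizures = [
        synthesize_seizure_connectivity(
            skeleton,
            lambdas[i],
            spec.within_noise_sd,
            noise_rng,
            n_windows=int(durations[i]),
            seizure_id=f"sz{i + 1:02d}",
        )
        for i in range(spec.n_seizures)
    ]
    return SyntheticCohort(
        spec=spec, times=times, latent=g, lambdas=lambdas, seizures=seizures, skeleton=skeleton
    )
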