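"""Sliding-window functional connectivity of ictal iEEG.

The feature space of the whole analysis: every 10-s seizure window is
described by band-averaged magnitude-squared coherence between all channel
pairs in six canonical frequency bands (delta through high-gamma).  Each
band's upper-triangle is L1-normalised to sum to one, so a window is a point
on a product of simplices and differences between windows reflect changes in
the *pattern* of network interactions rather than the global level of
coherence.  Seizures become pathways (sequences of such points) through this
network space.

Band-averaged coherence for channels i, j over band [f1, f2):

    C_ij = |sum_f P_ij(f)|^2 / (sum_f P_ii(f) * sum_f P_jj(f))

with auto/cross spectra P estimated by Welch's method (2-s segments,
1-s overlap, Hann taper) inside each 10-s window.  C_ij lies in [0, 1] by
Cauchy-Schwarz applied to the band-summed cross-spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import datetime
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import signal

__all__ = [
    "Band",
    "BandSet",
    "DEFAULT_BANDS",
    "Recording",
    "PreprocessConfig",
    "ConnectivityTimeSeries",
    "preprocess_recording",
    "band_coherence_window",
    "vectorize_normalize",
    "seizure_connectivity",
    "assemble_cohort_matrix",
    "n_channels_from_features",
]

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Band:
    name: str
    f1: float
    f2: float

    def __post_init__(self) -> None:
        if not 0 < self.f1 < self.f2:
            raise ValueError(f"band {self.name}: need 0 < f1 < f2")


@dataclass(frozen=True)
class BandSet:
    """Ordered, contiguous frequency bands.

    Band edges are treated as half-open intervals [f1, f2) on the discrete
    Welch grid so that shared edges (4, 8, 13, 30, 80 Hz) are not counted
    twice.
    """

    bands: tuple[Band, ...]

    def __post_init__(self) -> None:
        for a, b in zip(self.bands, self.bands[1:]):
            if not np.isclose(a.f2, b.f1):
                raise ValueError(f"bands {a.name} and {b.name} are not contiguous")

    def __len__(self) -> int:
        return len(self.bands)

    def __iter__(self):
        return iter(self.bands)

    @property
    def names(self) -> list[str]:
        return [b.name for b in self.bands]

    @property
    def fmax(self) -> float:
        return self.bands[-1].f2


DEFAULT_BANDS = BandSet(
    (
        Band("delta", 1.0, 4.0),
        Band("theta", 4.0, 8.0),
        Band("alpha", 8.0, 13.0),
        Band("beta", 13.0, 30.0),
        Band("gamma", 30.0, 80.0),
        Band("high_gamma", 80.0, 150.0),
    )
)


@dataclass
class Recording:
    """One seizure's multichannel iEEG clip.

    samples are channels x time in microvolts; missing_mask marks samples
    that were lost at acquisition and must be linearly interpolated (gaps
    longer than the configured maximum reject the seizure).
    """

    samples: np.ndarray
    fs: float
    channel_labels: list[str]
    seizure_id: str = ""
    onset_datetime: datetime | None = None
    missing_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be channels x time")
        if self.samples.shape[0] < 2:
            raise ValueError("need at least 2 channels")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError("channel_labels length mismatch")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.fs


@dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing parameters.

    Defaults follow standard clinical iEEG practice: 1-150 Hz fourth-order
    zero-phase Butterworth bandpass, 2-Hz-wide notches at the line frequency
    and its harmonics up to 150 Hz, gaps up to 50 ms linearly interpolated
    (a per-seizure override accommodates rare longer documented gaps), and
    re-referencing to the common average.
    """

    target_fs: float
    bandpass: tuple[float, float] = (1.0, 150.0)
    filter_order: int = 4
    line_freq: float = 50.0
    notch_width: float = 2.0
    max_gap_s: float = 0.05
    excluded_channels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        lo, hi = self.bandpass
        if not 0 < lo < hi < self.target_fs / 2:
            raise ValueError("bandpass must lie within (0, target_fs/2)")
        if self.line_freq not in (50.0, 60.0):
            raise ValueError("line_freq must be 50 or 60 Hz")

    @property
    def notch_freqs(self) -> list[float]:
        # harmonics up to the bandpass upper edge (150 Hz by default)
        top = self.bandpass[1]
        return [h * self.line_freq for h in range(1, int(top // self.line_freq) + 1)]


@dataclass
class ConnectivityTimeSeries:
    """Per-seizure matrix of window-wise coherence feature vectors.

    features is (6*(n^2-n)/2) x m, nonnegative, with every band block of
    every window summing to one.  band_block_index maps each feature row to
    its band (0..5); edge_index maps it to the (i, j) channel pair in
    row-major upper-triangle order.
    """

    features: np.ndarray
    band_block_index: np.ndarray
    window_start_times: np.ndarray
    edge_index: np.ndarray
    seizure_id: str = ""
    onset_datetime: datetime | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.band_block_index = np.asarray(self.band_block_index, dtype=int)
        self.window_start_times = np.asarray(self.window_start_times, dtype=float)
        self.edge_index = np.asarray(self.edge_index, dtype=int)
        if self.features.ndim != 2:
            raise ValueError("features must be 2-D (features x windows)")
        if self.band_block_index.shape[0] != self.features.shape[0]:
            raise ValueError("band_block_index length mismatch")

    @property
    def n_features(self) -> int:
        return self.features.shape[0]

    @property
    def n_windows(self) -> int:
        return self.features.shape[1]

    @property
    def n_bands(self) -> int:
        return int(self.band_block_index.max()) + 1

    def validate(self, atol: float = 1e-9) -> None:
        if np.any(self.features < 0):
            raise ValueError("connectivity features must be nonnegative")
        for b in range(self.n_bands):
            sums = self.features[self.band_block_index == b].sum(axis=0)
            if not np.allclose(sums, 1.0, atol=atol):
                raise ValueError(f"band block {b} does not sum to 1 in every window")


def n_channels_from_features(n_features: int, n_bands: int = 6) -> int:
    """Invert F = n_bands * n(n-1)/2 to recover the channel count."""
    e = n_features / n_bands
    n = int(round((1 + np.sqrt(1 + 8 * e)) / 2))
    if n_bands * (n * n - n) // 2 != n_features:
        raise ValueError(f"{n_features} features is not n_bands*(n^2-n)/2 for any n")
    return n


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def _interpolate_gaps(x: np.ndarray, mask: np.ndarray, fs: float, max_gap_s: float) -> np.ndarray:
    """Linearly interpolate masked runs; reject if any run exceeds max_gap_s."""
    out = x.copy()
    for ch in range(x.shape[0]):
        m = mask[ch]
        if not m.any():
            continue
        # run-length encode the mask
        edges = np.flatnonzero(np.diff(m.astype(int)))
        starts = np.flatnonzero(m[1:] & ~m[:-1]) + 1
        if m[0]:
            starts = np.r_[0, starts]
        ends = np.flatnonzero(~m[1:] & m[:-1]) + 1
        if m[-1]:
            ends = np.r_[ends, len(m)]
        del edges
        for s, e in zip(starts, ends):
            if (e - s) / fs > max_gap_s:
                raise ValueError(
                    f"missing-data gap of {(e - s) / fs:.3f} s exceeds "
                    f"max_gap_s={max_gap_s} s; seizure rejected"
                )
        good = ~m
        out[ch] = np.interp(np.arange(len(m)), np.flatnonzero(good), x[ch, good])
    return out


def _resample(x: np.ndarray, fs: float, target_fs: float) -> np.ndarray:
    if np.isclose(fs, target_fs):
        return x
    frac = Fraction(target_fs / fs).limit_denominator(1000)
    return signal.resample_poly(x, frac.numerator, frac.denominator, axis=-1)


def preprocess_recording(raw: Recording, config: PreprocessConfig) -> Recording:
    """Clean one seizure clip: exclude channels, interpolate short gaps,
    downsample, common-average re-reference, bandpass and notch (all filters
    fourth-order zero-phase Butterworth).

    Raises if the sampling rate cannot support the upper bandpass edge, if a
    gap exceeds ``config.max_gap_s``, or if fewer than two channels survive
    exclusion.
    """
    if raw.fs < 2 * config.bandpass[1]:
        raise ValueError(
            f"fs={raw.fs} Hz cannot resolve the {config.bandpass[1]}-Hz bandpass edge"
        )
    keep = [i for i, lab in enumerate(raw.channel_labels) if lab not in config.excluded_channels]
    if len(keep) < 2:
        raise ValueError("fewer than 2 channels remain after exclusions")
    x = raw.samples[keep]
    labels = [raw.channel_labels[i] for i in keep]

    if raw.missing_mask is not None and raw.missing_mask.any():
        # interpolate at the native rate, before the anti-alias resampler
        # would smear NaNs across the clip
        x = _interpolate_gaps(x, raw.missing_mask[keep], raw.fs, config.max_gap_s)
    if np.isnan(x).any():
        raise ValueError("NaNs present outside the declared missing_mask")

    x = _resample(x, raw.fs, config.target_fs)
    fs = config.target_fs

    x = x - x.mean(axis=0, keepdims=True)  # common average reference

    sos = signal.butter(config.filter_order, config.bandpass, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, x, axis=-1)
    for f0 in config.notch_freqs:
        half = config.notch_width / 2
        sos = signal.butter(
            config.filter_order, [f0 - half, f0 + half], btype="bandstop", fs=fs, output="sos"
        )
        x = signal.sosfiltfilt(sos, x, axis=-1)

    return replace(raw, samples=x, fs=fs, channel_labels=labels, missing_mask=None)


# ---------------------------------------------------------------------------
# Coherence
# ---------------------------------------------------------------------------


def _welch_spectra(
    window: np.ndarray, fs: float, welch_win: float, welch_overlap: float
) -> tuple[np.ndarray, np.ndarray]:
    """All auto- and cross-spectra of a window via Welch's method.

    Returns (freqs, P) with P of shape (n_ch, n_ch, n_freq); P[i, j] is the
    cross-spectrum of channels i and j (P[i, i] real and nonnegative).
    """
    n_ch, n_t = window.shape
    nper = int(round(welch_win * fs))
    step = nper - int(round(welch_overlap * fs))
    if n_t < nper:
        raise ValueError("window shorter than a Welch segment")
    starts = np.arange(0, n_t - nper + 1, step)
    taper = signal.windows.hann(nper, sym=False)
    segs = np.stack([window[:, s : s + nper] for s in starts], axis=1)  # (ch, seg, t)
    segs = segs - segs.mean(axis=-1, keepdims=True)
    X = np.fft.rfft(segs * taper, axis=-1)  # (ch, seg, f)
    freqs = np.fft.rfftfreq(nper, d=1 / fs)
    # scaling constants cancel in the coherence ratio
    P = np.einsum("isf,jsf->ijf", X, np.conj(X)) / len(starts)
    return freqs, P


def band_coherence_window(
    window: np.ndarray,
    fs: float,
    bands: BandSet = DEFAULT_BANDS,
    welch_win: float = 2.0,
    welch_overlap: float = 1.0,
) -> np.ndarray:
    """Band-averaged coherence matrices for one analysis window.

    Cross- and auto-spectra are summed over each band's discrete frequency
    bins ([f1, f2) half-open) before forming the magnitude-squared ratio, so
    the result is coherence "filtered in the frequency domain" to the band.

    Returns an array of shape (len(bands), n_ch, n_ch), each matrix symmetric
    with unit diagonal and entries in [0, 1].
    """
    window = np.asarray(window, dtype=float)
    if window.ndim != 2:
        raise ValueError("window must be channels x time")
    var = window.var(axis=-1)
    if np.any(var <= 0):
        bad = np.flatnonzero(var <= 0)
        raise ValueError(f"zero-variance channel(s) {bad.tolist()}: autospectrum degenerate")

    freqs, P = _welch_spectra(window, fs, welch_win, welch_overlap)
    out = np.empty((len(bands), window.shape[0], window.shape[0]))
    for k, band in enumerate(bands):
        sel = (freqs >= band.f1) & (freqs < band.f2)
        if not sel.any():
            raise ValueError(f"no Welch frequency bins in band {band.name}")
        S = P[:, :, sel].sum(axis=-1)
        auto = np.real(np.diag(S))
        if np.any(auto <= 0):
            raise ValueError(f"degenerate autospectrum in band {band.name}")
        C = np.abs(S) ** 2 / np.outer(auto, auto)
        out[k] = np.clip((C + C.T) / 2, 0.0, 1.0)
        np.fill_diagonal(out[k], 1.0)
    return out


def vectorize_normalize(matrices: np.ndarray) -> np.ndarray:
    """Upper-triangle vectorisation with per-band L1 normalisation.

    Each band's (n x n) coherence matrix contributes its strict upper
    triangle in row-major order; every band block is scaled to sum to one.
    """
    matrices = np.asarray(matrices, dtype=float)
    if matrices.ndim != 3 or matrices.shape[1] != matrices.shape[2]:
        raise ValueError("expected (n_bands, n, n) array of matrices")
    if np.any(matrices < 0):
        raise ValueError("coherence matrices must be nonnegative")
    n = matrices.shape[1]
    iu = np.triu_indices(n, k=1)
    blocks = []
    for k in range(matrices.shape[0]):
        v = matrices[k][iu]
        s = v.sum()
        if s <= 0:
            raise ValueError(f"band {k}: all-zero upper triangle, normalization undefined")
        blocks.append(v / s)
    return np.concatenate(blocks)


def _band_edge_indices(n_channels: int, n_bands: int) -> tuple[np.ndarray, np.ndarray]:
    iu = np.triu_indices(n_channels, k=1)
    edges = np.column_stack(iu)
    edge_index = np.tile(edges, (n_bands, 1))
    band_block_index = np.repeat(np.arange(n_bands), edges.shape[0])
    return band_block_index, edge_index


def seizure_connectivity(
    rec: Recording,
    config: PreprocessConfig | None = None,
    bands: BandSet = DEFAULT_BANDS,
    window_s: float = 10.0,
    step_s: float = 1.0,
    preprocess: bool = True,
) -> ConnectivityTimeSeries:
    """Full per-seizure connectivity: preprocess, slide a 10-s window at 1-s
    steps, and emit the per-window normalised coherence feature vectors.

    A seizure shorter than one window is rejected; a duration of d seconds
    yields m = floor(d - 10) + 1 windows.
    """
    if preprocess:
        if config is None:
            raise ValueError("config required when preprocess=True")
        rec = preprocess_recording(rec, config)
    if rec.duration_s < window_s:
        raise ValueError(
            f"seizure {rec.seizure_id or '?'} lasts {rec.duration_s:.1f} s "
            f"< {window_s} s window; rejected"
        )
    n_win = int(np.floor(rec.duration_s - window_s) / step_s) + 1
    starts_s = np.arange(n_win) * step_s
    wlen = int(round(window_s * rec.fs))
    cols = []
    for s in starts_s:
        i0 = int(round(s * rec.fs))
        mats = band_coherence_window(rec.samples[:, i0 : i0 + wlen], rec.fs, bands)
        cols.append(vectorize_normalize(mats))
    band_block_index, edge_index = _band_edge_indices(rec.n_channels, len(bands))
    return ConnectivityTimeSeries(
        features=np.column_stack(cols),
        band_block_index=band_block_index,
        window_start_times=starts_s,
        edge_index=edge_index,
        seizure_id=rec.seizure_id,
        onset_datetime=rec.onset_datetime,
    )


def assemble_cohort_matrix(
    seizures: Sequence[ConnectivityTimeSeries],
) -> tuple[np.ndarray, np.ndarray]:
    """Horizontally concatenate per-seizure features into the cohort matrix V.

    Returns (V, labels) where labels[k] is the index into ``seizures`` of the
    seizure owning column k.
    """
    if not seizures:
        raise ValueError("no seizures to assemble")
    dims = {s.n_features for s in seizures}
    if len(dims) != 1:
        raise ValueError(f"mixed feature dimensions {sorted(dims)}; one patient at a time")
    V = np.concatenate([s.features for s in seizures], axis=1)
    labels = np.concatenate([np.full(s.n_windows, i) for i, s in enumerate(seizures)])
    return V, labels
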