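"""File formats: EDF signals, HDF5 connectivity/NMF containers, CSV tables.

Raw multichannel signals travel as plain EDF (written here with a minimal
16-bit writer, read back through mne) or as a simple HDF5 signal container.
Connectivity time series and NMF models go to HDF5 with their index tables;
dissimilarity/temporal-distance matrices and TCPs go to CSV; seizure
annotations are CSV with one row per seizure.
"""

from __future__ import annotations

import json
from datetime import datetime
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .connectivity import ConnectivityTimeSeries, Recording
from .dissimilarity import DissimilarityMatrix
from .nmf import NMFModel
from .temporal import TemporalCorrelationPattern, TemporalDistanceMatrix

__all__ = [
    "write_edf",
    "read_edf",
    "write_signal_h5",
    "read_signal_h5",
    "write_connectivity_h5",
    "read_connectivity_h5",
    "write_nmf_h5",
    "read_nmf_h5",
    "write_matrix_csv",
    "read_dissimilarity_csv",
    "read_temporal_csv",
    "write_tcp_csv",
    "read_tcp_csv",
    "read_annotations",
]


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------


def write_edf(path, samples: np.ndarray, fs: float, channel_labels, start: datetime | None = None) -> None:
    """Write a multichannel signal as plain EDF (16-bit, 1-s data records).

    ``fs`` must be an integer number of samples per second; the signal is
    truncated to whole seconds.  Physical units are microvolts.
    """
    samples = np.asarray(samples, dtype=float)
    n_ch, n_t = samples.shape
    if len(channel_labels) != n_ch:
        raise ValueError("channel_labels length mismatch")
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1-s record
    n_rec = n_t // spr
    if n_rec < 1:
        raise ValueError("signal shorter than one 1-s data record")
    start = start or datetime(2000, 1, 1)

    pmin = samples.min(axis=1)
    pmax = samples.max(axis=1)
    flat = pmax - pmin <= 0
    pmax[flat] = pmin[flat] + 1.0
    dmin, dmax = -32768, 32767

    def pad(s: str, width: int) -> bytes:
        return s[:width].ljust(width).encode("ascii")

    header = b"".join(
        [
            pad("0", 8),
            pad("X X X X", 80),
            pad("synthetic", 80),
            pad(start.strftime("%d.%m.%y"), 8),
            pad(start.strftime("%H.%M.%S"), 8),
            pad(str(256 * (1 + n_ch)), 8),
            pad("", 44),
            pad(str(n_rec), 8),
            pad("1", 8),
            pad(str(n_ch), 4),
        ]
    )
    fields = [
        (16, [str(lab) for lab in channel_labels]),
        (80, ["" for _ in range(n_ch)]),  # transducer
        (8, ["uV" for _ in range(n_ch)]),
        (8, [f"{v:.6g}" for v in pmin]),
        (8, [f"{v:.6g}" for v in pmax]),
        (8, [str(dmin)] * n_ch),
        (8, [str(dmax)] * n_ch),
        (80, ["" for _ in range(n_ch)]),  # prefiltering
        (8, [str(spr)] * n_ch),
        (32, ["" for _ in range(n_ch)]),
    ]
    sig_header = b"".join(b"".join(pad(v, w) for v in vals) for w, vals in fields)

    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.round((samples[:, : n_rec * spr] - pmin[:, None]) * scale[:, None]) + dmin
    digital = np.clip(digital, dmin, dmax).astype("<i2")
    # interleave: record-major, channel blocks inside each record
    records = digital.reshape(n_ch, n_rec, spr).transpose(1, 0, 2)
    with open(path, "wb") as f:
        f.write(header + sig_header)
        f.write(records.tobytes())


def read_edf(path, seizure_id: str = "", onset_datetime: datetime | None = None) -> Recording:
    """Read an EDF file into a Recording via mne."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return Recording(
        samples=raw.get_data() * 1e6,  # mne returns volts
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        seizure_id=seizure_id,
        onset_datetime=onset_datetime,
    )


def write_signal_h5(path, samples: np.ndarray, fs: float, channel_labels) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=np.asarray(samples, dtype=float))
        f.attrs["fs"] = float(fs)
        f.create_dataset(
            "channel_labels", data=np.array([str(c) for c in channel_labels], dtype="S")
        )


def read_signal_h5(path, seizure_id: str = "") -> Recording:
    with h5py.File(path, "r") as f:
        return Recording(
            samples=np.asarray(f["samples"]),
            fs=float(f.attrs["fs"]),
            channel_labels=[c.decode() for c in f["channel_labels"]],
            seizure_id=seizure_id,
        )


# ---------------------------------------------------------------------------
# Connectivity and NMF containers
# ---------------------------------------------------------------------------


def write_connectivity_h5(path, cts: ConnectivityTimeSeries) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("features", data=cts.features)
        f.create_dataset("band_block_index", data=cts.band_block_index)
        f.create_dataset("window_start_times", data=cts.window_start_times)
        f.create_dataset("edge_index", data=cts.edge_index)
        f.attrs["seizure_id"] = cts.seizure_id
        if cts.onset_datetime is not None:
            f.attrs["onset_datetime"] = cts.onset_datetime.isoformat()


def read_connectivity_h5(path) -> ConnectivityTimeSeries:
    with h5py.File(path, "r") as f:
        onset = f.attrs.get("onset_datetime")
        return ConnectivityTimeSeries(
            features=np.asarray(f["features"]),
            band_block_index=np.asarray(f["band_block_index"]),
            window_start_times=np.asarray(f["window_start_times"]),
            edge_index=np.asarray(f["edge_index"]),
            seizure_id=str(f.attrs.get("seizure_id", "")),
            onset_datetime=datetime.fromisoformat(onset) if onset else None,
        )


def write_nmf_h5(path, model: NMFModel, stability: dict[int, float] | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("W", data=model.W)
        f.create_dataset("H", data=model.H)
        f.attrs["rank"] = model.rank
        f.attrs["seed"] = model.seed
        f.attrs["fit_error"] = model.fit_error
        f.attrs["converged"] = model.converged
        if stability:
            f.create_dataset("stability_ranks", data=sorted(stability))
            f.create_dataset("stability_scores", data=[stability[r] for r in sorted(stability)])


def read_nmf_h5(path) -> NMFModel:
    with h5py.File(path, "r") as f:
        return NMFModel(
            W=np.asarray(f["W"]),
            H=np.asarray(f["H"]),
            rank=int(f.attrs["rank"]),
            seed=int(f.attrs["seed"]),
            fit_error=float(f.attrs["fit_error"]),
            converged=bool(f.attrs["converged"]),
        )


# ---------------------------------------------------------------------------
# CSV tables
# ---------------------------------------------------------------------------


def write_matrix_csv(path, values: np.ndarray, ids) -> None:
    pd.DataFrame(values, index=list(ids), columns=list(ids)).to_csv(path)


def read_dissimilarity_csv(path) -> DissimilarityMatrix:
    df = pd.read_csv(path, index_col=0)
    return DissimilarityMatrix(values=df.to_numpy(dtype=float), seizure_ids=[str(c) for c in df.columns])


def read_temporal_csv(path) -> TemporalDistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    values = df.to_numpy(dtype=float)
    times = np.r_[0.0, np.cumsum(np.diag(values, k=1))]
    return TemporalDistanceMatrix(values=values, times=times)


def write_tcp_csv(path, tcp: TemporalCorrelationPattern) -> None:
    pd.DataFrame(
        {
            "timescale_days": tcp.timescales,
            "rho": tcp.rho,
            "n_pairs": tcp.n_pairs,
            "valid": tcp.valid.astype(int),
        }
    ).to_csv(path, index=False)


def read_tcp_csv(path) -> TemporalCorrelationPattern:
    df = pd.read_csv(path)
    return TemporalCorrelationPattern(
        timescales=df["timescale_days"].to_numpy(dtype=float),
        rho=df["rho"].to_numpy(dtype=float),
        n_pairs=df["n_pairs"].to_numpy(dtype=int),
        valid=df["valid"].to_numpy(dtype=bool),
    )


ANNOTATION_COLUMNS = ("seizure_id", "onset_datetime")


def read_annotations(path) -> pd.DataFrame:
    """Seizure annotation table: one row per seizure.

    Required columns: seizure_id, onset_datetime (ISO).  Optional:
    excluded_channels (semicolon-separated), line_freq, n_windows.
    Malformed rows raise an error naming the row and column.
    """
    df = pd.read_csv(path)
    for col in ANNOTATION_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"annotation table is missing required column {col!r}")
    for idx, row in df.iterrows():
        if not isinstance(row["seizure_id"], str) or not row["seizure_id"].strip():
            raise ValueError(f"row {idx}, column 'seizure_id': empty or non-string id")
        try:
            pd.Timestamp(row["onset_datetime"])
        except (ValueError, TypeError) as e:
            raise ValueError(f"row {idx}, column 'onset_datetime': {e}") from e
    df = df.copy()
    df["onset_datetime"] = pd.to_datetime(df["onset_datetime"], format="ISO8601")
    return df


def onset_days(onsets: pd.Series | list) -> np.ndarray:
    """Convert onset datetimes to fractional days since the first seizure."""
    ts = pd.to_datetime(pd.Series(list(onsets)))
    ts = ts.sort_values()
    delta = (ts - ts.iloc[0]).dt.total_seconds() / 86400.0
    return delta.to_numpy()


def save_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
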