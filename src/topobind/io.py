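"""Reading and writing the plain-text interchange formats.

EEG goes to/from CSV in the muselsl column layout (``timestamps`` followed
by one column per channel, microvolts); events and behavioral trials are
small CSVs. EDF reading is delegated to :mod:`mne` when it is installed.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .recording import EEGRecording

_FLOAT_FMT = "%.10g"


def write_eeg_csv(rec: EEGRecording, path: str | os.PathLike) -> None:
    """Write a recording as a muselsl-style CSV (timestamps + channels)."""
    t = np.arange(rec.n_samples) / rec.fs
    df = pd.DataFrame({"timestamps": t})
    for name in rec.channel_names:
        df[name] = rec.channel(name)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_eeg_csv(
    path: str | os.PathLike,
    fs: float | None = None,
    events: list[tuple[int, str]] | None = None,
) -> EEGRecording:
    """Read a muselsl-style CSV.

    The sampling rate is inferred from the timestamp column unless given
    explicitly (timestamps are assumed uniform).
    """
    df = pd.read_csv(path)
    if "timestamps" not in df.columns:
        raise ValueError(f"{path}: expected a 'timestamps' column")
    channels = [c for c in df.columns if c != "timestamps"]
    if fs is None:
        t = df["timestamps"].to_numpy(dtype=float)
        if len(t) < 2:
            raise ValueError(f"{path}: cannot infer fs from {len(t)} samples")
        fs = 1.0 / float(np.median(np.diff(t)))
    data = df[channels].to_numpy(dtype=float).T
    return EEGRecording(data, fs=fs, channel_names=tuple(channels),
                        events=list(events or []))


def write_events_csv(rec: EEGRecording, path: str | os.PathLike) -> None:
    """Write event markers as CSV (timestamp, label)."""
    rows = [(idx / rec.fs, label) for idx, label in rec.events]
    pd.DataFrame(rows, columns=["timestamp", "label"]).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_events_csv(path: str | os.PathLike, fs: float) -> list[tuple[int, str]]:
    """Read events CSV into (sample_index, label) pairs for a given fs."""
    df = pd.read_csv(path)
    return [(int(round(t * fs)), str(lab))
            for t, lab in zip(df["timestamp"], df["label"])]


def read_eeg_edf(path: str | os.PathLike) -> EEGRecording:
    """Read an EDF recording via mne (optional dependency)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ImportError("EDF support requires mne (pip install mne)") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    return EEGRecording(data, fs=float(raw.info["sfreq"]),
                        channel_names=tuple(raw.ch_names))


def write_trials_csv(trials, path: str | os.PathLike) -> None:
    """Write behavioral trials (see :mod:`topobind.binding`) as CSV."""
    rows = []
    for i, tr in enumerate(trials):
        rows.append({
            "trial": i,
            "condition": tr.condition,
            "actual_ms": tr.actual_ms,
            "reported_ms": tr.reported_ms,
            "actual_deg": tr.actual_deg,
            "reported_deg": tr.reported_deg,
            "clock_period_ms": tr.clock_period_ms,
            "valid": int(tr.valid),
        })
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_trials_csv(path: str | os.PathLike):
    """Read behavioral trials CSV back into TrialRecord objects."""
    from .binding import TrialRecord

    df = pd.read_csv(path)
    return [
        TrialRecord(
            condition=row["condition"],
            actual_deg=float(row["actual_deg"]),
            reported_deg=float(row["reported_deg"]),
            clock_period_ms=float(row["clock_period_ms"]),
            valid=bool(row.get("valid", 1)),
        )
        for _, row in df.iterrows()
    ]
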