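"""Waveform I/O: CSV/Parquet (time, value) series and Parquet window dumps.

Input series must be uniformly sampled per channel; the sampling rate is
taken from the time column (median spacing) unless given explicitly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError
from .records import WaveformRecord


def read_waveform(path, channel: str, subject_id: str = "",
                  fs: float | None = None) -> WaveformRecord:
    """Read one channel from a CSV or Parquet file with (time, value) columns."""
    path = Path(path)
    df = pd.read_parquet(path) if path.suffix == ".parquet" else pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "value" not in cols:
        raise DataError(f"{path} lacks a 'value' column")
    values = df[cols["value"]].to_numpy(dtype=float)
    if "time" in cols:
        t = df[cols["time"]].to_numpy(dtype=float)
        dt = np.diff(t)
        if t.size < 2 or np.any(dt <= 0):
            raise DataError(f"{path}: time column must be strictly increasing")
        step = float(np.median(dt))
        if np.max(np.abs(dt - step)) > 0.01 * step:
            raise DataError(f"{path}: sampling is not uniform")
        fs = fs or 1.0 / step
        t0 = float(t[0])
    else:
        if fs is None:
            raise DataError(f"{path} has no time column; pass fs explicitly")
        t0 = 0.0
    return WaveformRecord(subject_id=subject_id or path.stem, channel=channel,
                          samples=values, fs=float(fs), t0=t0)


def write_windows_parquet(windows: list[WaveformRecord], path) -> None:
    """Write filtered tumbling windows as one tidy Parquet table."""
    frames = []
    for w, rec in enumerate(windows):
        frames.append(pd.DataFrame({
            "subject_id": rec.subject_id, "channel": rec.channel, "window": w,
            "time": rec.t0 + np.arange(rec.n_samples) / rec.fs,
            "value": rec.samples}))
    pd.concat(frames, ignore_index=True).to_parquet(path)


def read_windows_parquet(path) -> list[WaveformRecord]:
    df = pd.read_parquet(path)
    out = []
    for (sid, ch, w), g in df.groupby(["subject_id", "channel", "window"], sort=True):
        t = g["time"].to_numpy(dtype=float)
        fs = 1.0 / float(np.median(np.diff(t)))
        out.append(WaveformRecord(subject_id=str(sid), channel=str(ch),
                                  samples=g["value"].to_numpy(dtype=float),
                                  fs=fs, t0=float(t[0])))
    return out
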