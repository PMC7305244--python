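"""Plain-text readers and writers for recordings and derived tables.

All formats are CSV: ECG (time_s, ch1, ch2, ch3), beat tables, RR-interval
tables, component tables, epoch tables, and cohort manifests.  Sampling rate
is taken from the time column when not given explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class RawRecording:
    """Three synchronized sampled ECG channels plus session metadata."""

    channels: np.ndarray  # (3, n)
    fs: float
    t0: float = 0.0
    injection_time_s: float | None = None
    agent: str = "NONE"
    subject_id: str | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        self.channels = np.atleast_2d(np.asarray(self.channels, dtype=float))
        if self.channels.shape[0] != 3:
            raise ValueError("expected exactly 3 channels")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.injection_time_s is not None and not (
            0.0 <= self.injection_time_s - self.t0 <= self.duration_s
        ):
            raise ValueError("injection time outside the recording")

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def time(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs


ECG_COLUMNS = ["time_s", "ch1", "ch2", "ch3"]


def read_ecg_csv(path: str | Path, fs: float | None = None) -> RawRecording:
    """Load a three-channel ECG CSV (columns time_s, ch1, ch2, ch3)."""
    df = pd.read_csv(path)
    missing = [c for c in ECG_COLUMNS[1:] if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: no ECG channel columns {missing} — is this an RR-interval "
            "table?  The detect stage needs raw ECG; run decompose on RRI input."
        )
    if fs is None:
        if "time_s" not in df.columns:
            raise ValueError(f"{path}: no time_s column and no fs given")
        dt = np.median(np.diff(df["time_s"].to_numpy(float)))
        fs = 1.0 / dt
    t0 = float(df["time_s"].iloc[0]) if "time_s" in df.columns else 0.0
    channels = df[["ch1", "ch2", "ch3"]].to_numpy(float).T
    return RawRecording(channels=channels, fs=float(fs), t0=t0)


def write_ecg_csv(rec: RawRecording, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "time_s": rec.time(),
            "ch1": rec.channels[0],
            "ch2": rec.channels[1],
            "ch3": rec.channels[2],
        }
    )
    df.to_csv(path, index=False, float_format="%.6g")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_rri_csv(path: str | Path):
    from .detect import RRISequence

    df = pd.read_csv(path)
    needed = {"time_s", "rri_ms", "valid", "gap"}
    if not needed.issubset(df.columns):
        raise ValueError(f"{path}: RRI table needs columns {sorted(needed)}")
    return RRISequence.from_frame(df)


def read_components_csv(path: str | Path):
    from .decompose import RRComponents

    return RRComponents.from_frame(pd.read_csv(path))


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    needed = {"subject", "group", "agent", "injection_time_s"}
    if not needed.issubset(df.columns):
        raise ValueError(f"{path}: manifest needs columns {sorted(needed)}")
    return df
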