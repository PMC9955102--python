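"""Waveform records, monitor-export CSV I/O, and the ICP filtering chain.

Monitor exports are plain CSV with a header row and columns for time (s),
ICP (mmHg) and, when a balloon-inflation protocol is running, balloon
volume (mL).  The cleaning chain mirrors bedside practice for 200 Hz ICP:
an order-4 Butterworth band-stop notch around the 50 Hz powerline
frequency followed by an order-4 Butterworth low-pass at 60 Hz, both
applied forward–backward (zero phase) so windowed statistics stay aligned
with the raw signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "WaveformRecord",
    "FilterConfig",
    "ColumnMap",
    "read_waveform_csv",
    "write_waveform_csv",
    "filter_icp",
]

logger = logging.getLogger(__name__)

_STEP_RTOL = 1e-6  # relative tolerance on the sampling step


@dataclass(frozen=True)
class ColumnMap:
    """CSV column names (comma delimiter, '.' decimal, UTF-8 assumed)."""

    time: str = "time_s"
    icp: str = "icp_mmhg"
    volume: str = "balloon_ml"


@dataclass(frozen=True)
class WaveformRecord:
    """A uniformly sampled ICP recording, optionally with balloon volume.

    Attributes
    ----------
    icp : numpy.ndarray
        Intracranial pressure in mmHg.
    fs : float
        Sampling rate in Hz (monitor default 200).
    t : numpy.ndarray
        Time in seconds, uniform grid with step ``1/fs``.
    volume : numpy.ndarray or None
        Balloon volume in mL, aligned with ``icp``.
    """

    icp: np.ndarray
    fs: float = 200.0
    t: np.ndarray | None = None
    volume: np.ndarray | None = None

    def __post_init__(self) -> None:
        icp = np.asarray(self.icp, dtype=float)
        if icp.ndim != 1:
            raise ValueError("icp must be 1-D")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        object.__setattr__(self, "icp", icp)
        if self.t is None:
            object.__setattr__(self, "t", np.arange(icp.size) / self.fs)
        else:
            t = np.asarray(self.t, dtype=float)
            if t.shape != icp.shape:
                raise ValueError("t and icp must have equal length")
            if t.size > 1:
                steps = np.diff(t)
                step = 1.0 / self.fs
                if (steps <= 0).any() or np.abs(steps - step).max() > _STEP_RTOL * max(step, 1.0) + 1e-9:
                    raise ValueError("time vector must increase uniformly with step 1/fs")
            object.__setattr__(self, "t", t)
        if self.volume is not None:
            v = np.asarray(self.volume, dtype=float)
            if v.shape != icp.shape:
                raise ValueError("volume and icp must have equal length")
            object.__setattr__(self, "volume", v)

    def __len__(self) -> int:
        return self.icp.size

    @property
    def duration_s(self) -> float:
        return self.icp.size / self.fs

    def with_icp(self, icp: np.ndarray) -> "WaveformRecord":
        """Copy of this record with the ICP channel replaced."""
        return replace(self, icp=np.asarray(icp, dtype=float))


def read_waveform_csv(
    path: str | Path,
    columns: ColumnMap = ColumnMap(),
    *,
    fs: float | None = None,
) -> WaveformRecord:
    """Read a monitor-export CSV into a :class:`WaveformRecord`.

    Rows whose ICP value does not parse as a number are dropped (the count
    is logged).  If the time column is present the sampling rate is inferred
    from the median step and the grid is checked for uniformity; otherwise
    ``fs`` must be supplied (default 200 Hz) and time is synthesized.
    Lines starting with ``#`` are treated as comments.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    if columns.icp not in df.columns:
        raise ValueError(f"required column {columns.icp!r} not found in {path.name} "
                         f"(columns: {list(df.columns)})")
    icp = pd.to_numeric(df[columns.icp], errors="coerce")
    bad = icp.isna()
    if bad.any():
        logger.warning("%s: dropped %d rows with unparseable ICP", path.name, int(bad.sum()))
        df = df.loc[~bad.values]
        icp = icp.loc[~bad.values]
    icp = icp.to_numpy(dtype=float)

    volume = None
    if columns.volume in df.columns:
        volume = pd.to_numeric(df[columns.volume], errors="coerce").to_numpy(dtype=float)

    if columns.time in df.columns:
        t = pd.to_numeric(df[columns.time], errors="coerce").to_numpy(dtype=float)
        if np.isnan(t).any() or (np.diff(t) <= 0).any():
            raise ValueError(f"{path.name}: time column must be numeric and strictly increasing")
        if t.size > 1:
            steps = np.diff(t)
            step = float(np.median(steps))
            if np.abs(steps - step).max() > _STEP_RTOL * max(step, 1.0) + 1e-9:
                raise ValueError(f"{path.name}: non-uniform sampling step")
            inferred_fs = 1.0 / step
        else:
            inferred_fs = fs if fs is not None else 200.0
        return WaveformRecord(icp=icp, fs=inferred_fs, t=t, volume=volume)

    if fs is None:
        fs = 200.0
    return WaveformRecord(icp=icp, fs=fs, volume=volume)


def write_waveform_csv(
    record: WaveformRecord,
    path: str | Path,
    columns: ColumnMap = ColumnMap(),
    *,
    float_format: str = "%.10g",
) -> Path:
    """Write a record to CSV, losslessly round-trippable at ``float_format``."""
    path = Path(path)
    data = {columns.time: record.t, columns.icp: record.icp}
    if record.volume is not None:
        data[columns.volume] = record.volume
    pd.DataFrame(data).to_csv(path, index=False, float_format=float_format)
    return path


@dataclass(frozen=True)
class FilterConfig:
    """Parameters of the notch + low-pass cleaning chain."""

    notch_center_hz: float = 50.0
    notch_halfwidth_hz: float = 2.0
    lowpass_hz: float = 60.0
    order: int = 4
    zero_phase: bool = True


def filter_icp(record: WaveformRecord, cfg: FilterConfig = FilterConfig()) -> WaveformRecord:
    """Apply the band-stop (powerline) then low-pass Butterworth chain.

    Both filters are order ``cfg.order`` Butterworth designs; with
    ``zero_phase`` they are run forward–backward (doubling the effective
    order, zero phase shift).  Output length equals input length; time and
    volume channels pass through untouched.

    Raises
    ------
    ValueError
        If the low-pass cutoff or notch band reaches the Nyquist frequency.
    """
    nyq = record.fs / 2.0
    hi = cfg.notch_center_hz + cfg.notch_halfwidth_hz
    if cfg.lowpass_hz >= nyq or hi >= nyq:
        raise ValueError(
            f"filter bands (notch up to {hi} Hz, low-pass {cfg.lowpass_hz} Hz) must lie "
            f"below the Nyquist frequency {nyq} Hz"
        )
    lo = cfg.notch_center_hz - cfg.notch_halfwidth_hz
    if lo <= 0:
        raise ValueError("notch band must lie above 0 Hz")

    sos_notch = signal.butter(cfg.order, [lo, hi], btype="bandstop", fs=record.fs, output="sos")
    sos_low = signal.butter(cfg.order, cfg.lowpass_hz, btype="low", fs=record.fs, output="sos")
    x = record.icp
    if cfg.zero_phase:
        x = signal.sosfiltfilt(sos_notch, x)
        x = signal.sosfiltfilt(sos_low, x)
    else:
        x = signal.sosfilt(sos_notch, x)
        x = signal.sosfilt(sos_low, x)
    return record.with_icp(x)
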