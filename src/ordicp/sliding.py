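"""Sliding-window ordinal-complexity tracks over an ICP waveform.

Each window of ``window_len`` samples (default 3600 = 5 * 6! at 200 Hz,
i.e. 18 s) advanced by ``shift`` samples (default 1000 = 5 s) yields one
row of the monitoring track: permutation entropy, normalized number of
missing patterns, the probabilities of the fully ascending and fully
descending patterns, and the window-mean ICP.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ordinal import EmbeddingConfig, entropy_from_counts, symbolize
from .preprocessing import WaveformRecord

__all__ = ["WindowTrack", "window_starts", "analyze", "sweep_m"]

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_LEN = 3600
DEFAULT_SHIFT = 1000


def window_starts(T: int, window_len: int, shift: int) -> np.ndarray:
    """Start indices of complete sliding windows.

    Windows are 0-based, half-open ``[start, start + window_len)``; the
    trailing incomplete window is dropped.  Returns an empty vector when no
    complete window fits.
    """
    if window_len < 1 or shift < 1:
        raise ValueError("window_len and shift must be >= 1")
    if T < window_len:
        return np.empty(0, dtype=np.int64)
    return np.arange(0, T - window_len + 1, shift, dtype=np.int64)


@dataclass(frozen=True)
class WindowTrack:
    """Per-window complexity features of one recording."""

    window_start_idx: np.ndarray
    pe: np.ndarray
    nmp_norm: np.ndarray
    p_first: np.ndarray
    p_last: np.ndarray
    mean_icp: np.ndarray
    window_len: int
    shift: int
    m: int
    tau: int
    fs: float = 200.0

    def __post_init__(self) -> None:
        n = self.window_start_idx.size
        for name in ("pe", "nmp_norm", "p_first", "p_last", "mean_icp"):
            if getattr(self, name).size != n:
                raise ValueError(f"track vector {name!r} length mismatch")

    def __len__(self) -> int:
        return self.window_start_idx.size

    def to_frame(self) -> pd.DataFrame:
        """Track as a tidy DataFrame (one row per window)."""
        return pd.DataFrame(
            {
                "window_start_idx": self.window_start_idx,
                "t_start_s": self.window_start_idx / self.fs,
                "mean_icp_mmhg": self.mean_icp,
                "pe": self.pe,
                "nmp_norm": self.nmp_norm,
                "p_first": self.p_first,
                "p_last": self.p_last,
            }
        )


def analyze(
    record: WaveformRecord,
    cfg: EmbeddingConfig = EmbeddingConfig(),
    window_len: int = DEFAULT_WINDOW_LEN,
    shift: int = DEFAULT_SHIFT,
) -> WindowTrack:
    """Compute the per-window ordinal-complexity track of a waveform.

    The whole series is symbolized once; each window's pattern distribution
    is tabulated from the contiguous slice of ranks whose embedded vectors
    start inside the window.  ``mean_icp`` is the arithmetic mean of the
    window's samples of ``record.icp`` (the signal handed in — filter first
    if filtered means are wanted).

    Raises
    ------
    ValueError
        If the record does not contain a single complete window.
    """
    n_pat = cfg.n_patterns
    n_vec_per_window = window_len - (cfg.m - 1) * cfg.tau
    if n_vec_per_window < n_pat:
        warnings.warn(
            f"window holds {n_vec_per_window} embedded vectors, fewer than m! = {n_pat}; "
            "pattern probabilities will be sparse",
            stacklevel=2,
        )
    starts = window_starts(len(record), window_len, shift)
    if starts.size == 0:
        raise ValueError(
            f"record of {len(record)} samples is shorter than one {window_len}-sample window"
        )
    ranks = symbolize(record.icp, cfg)

    n_w = starts.size
    pe = np.empty(n_w)
    nmp = np.empty(n_w)
    p_first = np.empty(n_w)
    p_last = np.empty(n_w)
    mean_icp = np.empty(n_w)
    for k, s in enumerate(starts):
        sub = ranks[s : s + n_vec_per_window]
        counts = np.bincount(sub, minlength=n_pat + 1)[1:]
        n_vec = sub.size
        pe[k] = entropy_from_counts(counts, n_vec)
        nmp[k] = (counts == 0).sum() / n_pat
        p_first[k] = counts[0] / n_vec
        p_last[k] = counts[-1] / n_vec
        mean_icp[k] = record.icp[s : s + window_len].mean()

    return WindowTrack(
        window_start_idx=starts,
        pe=pe,
        nmp_norm=nmp,
        p_first=p_first,
        p_last=p_last,
        mean_icp=mean_icp,
        window_len=window_len,
        shift=shift,
        m=cfg.m,
        tau=cfg.tau,
        fs=record.fs,
    )


def sweep_m(
    record: WaveformRecord,
    m_values: tuple[int, ...] = (3, 4, 5, 6, 7),
    tau: int = 1,
) -> pd.DataFrame:
    """Mean PE for several embedding dimensions, window length ``5 * m!``.

    One row per ``m`` with columns ``m``, ``window_len``, ``mean_pe``,
    ``n_windows`` and ``ok``.  An ``m`` whose window does not fit the record
    is flagged (``ok = False``, ``mean_pe = NaN``) rather than dropped.
    Windows do not overlap here (shift = window length).
    """
    rows = []
    for m in m_values:
        wl = 5 * math.factorial(m)
        try:
            track = analyze(record, EmbeddingConfig(m=m, tau=tau), window_len=wl, shift=wl)
            rows.append({"m": m, "window_len": wl, "mean_pe": float(track.pe.mean()),
                         "n_windows": len(track), "ok": True})
        except ValueError as exc:
            logger.warning("sweep_m: m=%d skipped (%s)", m, exc)
            rows.append({"m": m, "window_len": wl, "mean_pe": float("nan"),
                         "n_windows": 0, "ok": False})
    return pd.DataFrame(rows)
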