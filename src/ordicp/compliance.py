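"""Windowed intracranial-compliance estimation, ICC = dV/dICP.

Intracranial compliance measures how much volume the cranio-spinal system
can absorb per unit pressure rise.  With a balloon-volume channel recorded
alongside ICP, it is estimated here by finite differences of successive
window means: robust against pulse-level noise, and aligned with the
sliding-window complexity track so the two can be compared window by
window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocessing import WaveformRecord
from .sliding import DEFAULT_SHIFT, DEFAULT_WINDOW_LEN, window_starts

__all__ = ["ComplianceTrack", "compliance_track"]

#: windows with |dICP| below this (mmHg) give no usable compliance estimate
DEFAULT_DICP_EPS = 0.1


@dataclass(frozen=True)
class ComplianceTrack:
    """Per-window compliance estimates; undefined entries are NaN."""

    window_start_idx: np.ndarray
    dv: np.ndarray        # mL, mean-volume increment from previous window
    dicp: np.ndarray      # mmHg, mean-ICP increment from previous window
    icc: np.ndarray       # mL/mmHg, NaN where |dicp| < eps or no predecessor

    def __len__(self) -> int:
        return self.window_start_idx.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "window_start_idx": self.window_start_idx,
                "dv_ml": self.dv,
                "dicp_mmhg": self.dicp,
                "icc_ml_per_mmhg": self.icc,
            }
        )


def compliance_track(
    record: WaveformRecord,
    window_len: int = DEFAULT_WINDOW_LEN,
    shift: int = DEFAULT_SHIFT,
    *,
    eps: float = DEFAULT_DICP_EPS,
) -> ComplianceTrack:
    """Estimate ICC per window from paired volume and ICP channels.

    Uses the same windowing as the complexity track.  For window ``k``,
    ``dv`` and ``dicp`` are the differences of window-mean volume and
    window-mean ICP with window ``k-1``; ``icc = dv / dicp`` where
    ``|dicp| >= eps``, NaN otherwise.  The first window has no predecessor
    and is always NaN.

    Raises
    ------
    ValueError
        If the record has no volume channel or no complete window.
    """
    if record.volume is None:
        raise ValueError("compliance estimation requires a balloon-volume channel")
    starts = window_starts(len(record), window_len, shift)
    if starts.size == 0:
        raise ValueError(
            f"record of {len(record)} samples is shorter than one {window_len}-sample window"
        )
    mean_v = np.array([record.volume[s : s + window_len].mean() for s in starts])
    mean_p = np.array([record.icp[s : s + window_len].mean() for s in starts])

    dv = np.full(starts.size, np.nan)
    dicp = np.full(starts.size, np.nan)
    dv[1:] = np.diff(mean_v)
    dicp[1:] = np.diff(mean_p)
    with np.errstate(invalid="ignore", divide="ignore"):
        icc = np.where(np.abs(dicp) >= eps, dv / dicp, np.nan)
    return ComplianceTrack(window_start_idx=starts, dv=dv, dicp=dicp, icc=icc)
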