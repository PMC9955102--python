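"""Three-stage rule classifier for ordinal-complexity windows.

The rule set summarizes the regimes seen in the porcine balloon-inflation
experiments:

* **injury-free** — PE above 0.3, normalized NMP below 90%, and the
  ascending pattern more probable than the descending one
  (``p(s1) > p(s_m!)``);
* **terminal** — normalized NMP at or above 95% with the descending
  pattern dominant (``p(s_m!) > p(s1)``);
* **intermediate** — normalized NMP between 90% and 95%, the band spanned
  by reversible hypertension episodes;
* **indeterminate** — none of the above; the rules are neither mutually
  exclusive nor exhaustive, so an explicit fall-through label is kept
  rather than forcing a choice.

Rules are evaluated in the fixed order injury_free → terminal →
intermediate → indeterminate; exactly one label results.  The features use
only the ordinal statistics, never the absolute ICP level.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .sliding import WindowTrack

__all__ = ["StageLabel", "StageThresholds", "classify_window", "classify_track"]


class StageLabel(str, Enum):
    INJURY_FREE = "injury_free"
    INTERMEDIATE = "intermediate"
    TERMINAL = "terminal"
    INDETERMINATE = "indeterminate"

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class StageThresholds:
    """Cut-offs of the rule table (proof-of-concept values, configurable)."""

    pe_min_healthy: float = 0.3
    nmp_max_healthy: float = 0.90
    nmp_min_terminal: float = 0.95

    def __post_init__(self) -> None:
        if not 0 < self.pe_min_healthy < 1:
            raise ValueError("pe_min_healthy must lie in (0, 1)")
        if not 0 < self.nmp_max_healthy <= self.nmp_min_terminal < 1:
            raise ValueError("need 0 < nmp_max_healthy <= nmp_min_terminal < 1")


def classify_window(
    pe: float,
    nmp_norm: float,
    p_first: float,
    p_last: float,
    thresholds: StageThresholds = StageThresholds(),
) -> StageLabel:
    """Classify one window from its ordinal features.

    Boundary semantics follow the quoted inequalities: healthy requires
    ``nmp_norm`` strictly below 0.90, terminal requires ``nmp_norm >= 0.95``,
    and the intermediate band is the half-open ``[0.90, 0.95)`` — plus
    every ``nmp_norm >= 0.95`` window lacking descending-pattern dominance
    falls through to intermediate only if below 0.95, otherwise
    indeterminate.
    """
    feats = {"pe": pe, "nmp_norm": nmp_norm, "p_first": p_first, "p_last": p_last}
    for name, v in feats.items():
        if not np.isfinite(v) or not 0.0 <= v <= 1.0:
            raise ValueError(f"feature {name}={v!r} outside [0, 1]")
    th = thresholds
    if pe > th.pe_min_healthy and nmp_norm < th.nmp_max_healthy and p_first > p_last:
        return StageLabel.INJURY_FREE
    if nmp_norm >= th.nmp_min_terminal and p_last > p_first:
        return StageLabel.TERMINAL
    if th.nmp_max_healthy <= nmp_norm < th.nmp_min_terminal:
        return StageLabel.INTERMEDIATE
    return StageLabel.INDETERMINATE


def classify_track(
    track: WindowTrack | pd.DataFrame,
    thresholds: StageThresholds = StageThresholds(),
) -> list[StageLabel]:
    """Elementwise :func:`classify_window` over a track; length preserved."""
    if isinstance(track, WindowTrack):
        frame = track.to_frame()
    else:
        frame = track
    return [
        classify_window(row.pe, row.nmp_norm, row.p_first, row.p_last, thresholds)
        for row in frame.itertuples()
    ]
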