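"""Synthetic monitor-style ICP + balloon-volume recordings.

Emulates the three stages of a porcine balloon-inflation experiment so the
whole pipeline can be exercised without animal data:

* **stage 1** — baseline: balloon empty, mean ICP near 5 mmHg, pulsatile
  waveform with plenty of beat-to-beat variability;
* **stage 2** — reversible intracranial hypertension: saline inflation of
  an epidural balloon raises ICP through an exponential pressure–volume
  relation, then deflation at 1 mL/min returns it to baseline;
* **stage 3** — terminal high-ICP state: high sustained volume and a
  near-periodic, low-variability waveform.

Model
-----
``ICP(t) = p0 + p1 * exp(E * V(t)) + pulse(t) + noise(t) + powerline(t)``

The cardiac pulse is a phase-warped sinusoid with harmonics (emulating the
P1/P2/P3 percussion–tidal–dicrotic morphology), amplitude-modulated by
respiration and growing with mean ICP.  Its *asymmetry* flips with injury
severity: at baseline the rising limb is the longer one (ascending
6-sample runs dominate), under hypertension the upstroke sharpens and the
decay lengthens (descending runs dominate) — reproducing the observed
reversal of p(s1) vs p(s720).

Beat-to-beat stochasticity (heart-period jitter, amplitude jitter, and
band-limited physiologic noise) is scaled by a *complexity factor*
``c(t) = 1 - complexity_coupling * severity(t)`` that shrinks as mean ICP
rises, encoding the loss-of-complexity hypothesis into the generator: PE
falls and missing patterns rise during hypertension by construction.
Stage-3 segments force ``c`` to a small floor (near-periodic waveform).

All randomness flows from a single :class:`numpy.random.Generator` seeded
by ``SimConfig.seed``; identical configs give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from .preprocessing import WaveformRecord

__all__ = ["Segment", "SimConfig", "volume_protocol", "generate", "make_experiment"]

#: severity ramps from 0 at baseline mean ICP to 1 at this mean ICP (mmHg),
#: just above the 20 mmHg treatment threshold
SEVERITY_REF_ICP = 25.0

#: complexity floor used inside stage-3 segments (near-periodic waveform)
STAGE3_COMPLEXITY = 0.02


@dataclass(frozen=True)
class Segment:
    """One experimental segment: stage id, duration, balloon target.

    ``regime`` is the ground-truth annotation used by end-to-end tests
    ("baseline", "plateau", "recovery", "transition", "terminal", ...).
    """

    stage: int
    duration_s: float
    target_volume_ml: float
    regime: str = ""

    def __post_init__(self) -> None:
        if self.stage not in (1, 2, 3):
            raise ValueError(f"stage must be 1, 2 or 3, got {self.stage}")
        if self.duration_s <= 0:
            raise ValueError("segment duration must be positive")
        if self.target_volume_ml < 0:
            raise ValueError("balloon volume cannot be negative")


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults emulate the 200 Hz pig protocol."""

    fs: float = 200.0
    heart_rate_hz: float = 1.8
    resp_rate_hz: float = 0.25
    p0_mmhg: float = 2.0          # pressure offset of the P–V curve
    p1_mmhg: float = 3.0          # exponential scale (baseline mean = p0 + p1)
    elastance_per_ml: float = 0.3  # E in ICP = p0 + p1*exp(E*V)
    pulse_amp_mmhg: float = 2.0   # baseline cardiac half-amplitude
    noise_sd_mmhg: float = 0.3    # physiologic noise SD at full complexity
    powerline_amp_mmhg: float = 0.2
    powerline_hz: float = 50.0
    complexity_coupling: float = 0.8  # in [0,1]; 0 = no loss of complexity
    seed: int = 0
    stage_plan: tuple[Segment, ...] = field(default_factory=tuple)
    deflation_rate_ml_per_min: float = 1.0
    inflation_rate_ml_per_min: float = 2.0
    resp_mod_depth: float = 0.25

    def __post_init__(self) -> None:
        for name in ("fs", "heart_rate_hz", "resp_rate_hz", "deflation_rate_ml_per_min",
                     "inflation_rate_ml_per_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.powerline_amp_mmhg > 0 and self.fs <= 2 * self.powerline_hz:
            raise ValueError("fs must exceed twice the powerline frequency")
        if not 0.0 <= self.complexity_coupling <= 1.0:
            raise ValueError("complexity_coupling must lie in [0, 1]")
        object.__setattr__(self, "stage_plan", tuple(self.stage_plan))


def volume_protocol(
    stage_plan: tuple[Segment, ...] | list[Segment],
    deflation_rate_ml_per_min: float = 1.0,
    fs: float = 200.0,
    inflation_rate_ml_per_min: float = 2.0,
) -> np.ndarray:
    """Piecewise-linear balloon-volume trace for a segment plan.

    Within each segment the volume ramps from its previous value toward the
    segment target — at ``inflation_rate_ml_per_min`` when rising, at
    ``deflation_rate_ml_per_min`` when falling — and holds at the target for
    the remainder of the segment.  A segment too short for its ramp ends
    mid-ramp.  Volume starts at 0 mL.
    """
    chunks = []
    v = 0.0
    for seg in stage_plan:
        n = int(round(seg.duration_s * fs))
        t_rel = np.arange(n) / fs
        target = seg.target_volume_ml
        rate = (inflation_rate_ml_per_min if target >= v else deflation_rate_ml_per_min) / 60.0
        step = np.sign(target - v) * rate
        ramp = v + step * t_rel
        ramp = np.clip(ramp, min(v, target), max(v, target))
        chunks.append(ramp)
        v = float(ramp[-1]) if n else v
    if not chunks:
        return np.empty(0)
    return np.concatenate(chunks)


def _smooth_noise(rng: np.random.Generator, n: int, cutoff_hz: float, fs: float) -> np.ndarray:
    """Unit-SD low-pass-filtered Gaussian noise (band-limited jitter source)."""
    w = rng.standard_normal(n)
    if n < 20:
        return w
    sos = signal.butter(2, cutoff_hz, btype="low", fs=fs, output="sos")
    x = signal.sosfilt(sos, w)
    sd = x.std()
    return x / sd if sd > 0 else x


def _stage_vector(stage_plan: tuple[Segment, ...], fs: float) -> np.ndarray:
    parts = [np.full(int(round(s.duration_s * fs)), s.stage, dtype=np.int64) for s in stage_plan]
    return np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)


def generate(cfg: SimConfig) -> WaveformRecord:
    """Generate a synthetic ICP + volume recording for ``cfg.stage_plan``."""
    if not cfg.stage_plan:
        raise ValueError("stage_plan is empty; nothing to generate")
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.fs
    volume = volume_protocol(
        cfg.stage_plan, cfg.deflation_rate_ml_per_min, fs, cfg.inflation_rate_ml_per_min
    )
    n = volume.size
    t = np.arange(n) / fs
    stage = _stage_vector(cfg.stage_plan, fs)

    mean = cfg.p0_mmhg + cfg.p1_mmhg * np.exp(cfg.elastance_per_ml * volume)
    baseline_mean = cfg.p0_mmhg + cfg.p1_mmhg
    severity = np.clip((mean - baseline_mean) / (SEVERITY_REF_ICP - baseline_mean), 0.0, 1.0)

    # complexity factor: 1 at healthy baseline, small under severe hypertension,
    # floored near zero in stage-3 (terminal) segments
    c = 1.0 - cfg.complexity_coupling * severity
    c = np.where(stage == 3, STAGE3_COMPLEXITY, c)

    # --- cardiac pulse -----------------------------------------------------
    # heart-period jitter: slowly varying instantaneous rate
    rate_jit = _smooth_noise(rng, n, 0.5, fs)
    f_inst = cfg.heart_rate_hz * (1.0 + 0.04 * c * rate_jit)
    phase = 2.0 * np.pi * np.cumsum(f_inst) / fs

    # morphology: phase warp flips asymmetry with severity
    #   beta < 0 -> slow rise / fast fall (baseline, ascending runs dominate)
    #   beta > 0 -> fast rise / slow decay (hypertension/terminal)
    w = severity.copy()
    w[stage == 3] = 1.0
    beta = -0.6 * (1.0 - w) + 0.55 * w
    psi = phase + beta * np.sin(phase)
    harm = 1.0 - 0.5 * w  # terminal waveform loses harmonic content
    shape = (
        np.sin(psi)
        + 0.22 * harm * np.sin(2.0 * psi + 1.0)
        + 0.10 * harm * np.sin(3.0 * psi + 1.6)
    )

    # respiration modulates pulse amplitude; pulse grows with mean ICP
    resp = 1.0 + cfg.resp_mod_depth * np.sin(2.0 * np.pi * cfg.resp_rate_hz * t)
    amp_jit = 1.0 + 0.15 * c * _smooth_noise(rng, n, 0.8, fs)
    amp = cfg.pulse_amp_mmhg * (1.0 + severity) * resp * amp_jit
    pulse = 0.5 * amp * shape

    # --- stochastic components --------------------------------------------
    colored = _smooth_noise(rng, n, 3.0, fs)       # respiratory-band variability
    white = rng.standard_normal(n)                 # broadband sensor floor
    noise = cfg.noise_sd_mmhg * c * (colored + 0.12 * white)

    powerline = cfg.powerline_amp_mmhg * np.sin(
        2.0 * np.pi * cfg.powerline_hz * t + rng.uniform(0.0, 2.0 * np.pi)
    )

    icp = mean + pulse + noise + powerline
    return WaveformRecord(icp=icp, fs=fs, volume=volume)


# --- experiment presets ----------------------------------------------------

def _preset_plan(preset: str) -> tuple[Segment, ...]:
    if preset == "baseline":
        return (Segment(1, 120.0, 0.0, "baseline"),)
    if preset == "reversible_episode":
        return (
            Segment(1, 60.0, 0.0, "baseline"),
            Segment(2, 240.0, 7.0, "inflation"),
            Segment(2, 180.0, 7.0, "plateau"),
            Segment(2, 450.0, 0.0, "recovery"),
        )
    if preset == "terminal":
        return (
            Segment(3, 240.0, 8.0, "transition"),
            Segment(3, 240.0, 8.0, "terminal"),
        )
    if preset == "full_timeline":
        return (
            Segment(1, 180.0, 0.0, "baseline"),
            Segment(2, 240.0, 7.0, "inflation"),
            Segment(2, 180.0, 7.0, "plateau"),
            Segment(2, 450.0, 0.0, "recovery"),
            Segment(3, 240.0, 8.0, "transition"),
            Segment(3, 240.0, 8.0, "terminal"),
        )
    raise ValueError(f"unknown preset {preset!r}")


def annotations_for(plan: tuple[Segment, ...], fs: float = 200.0) -> pd.DataFrame:
    """Segment table (start/end seconds and sample indices, stage, regime)."""
    rows = []
    t0 = 0.0
    i0 = 0
    for seg in plan:
        n = int(round(seg.duration_s * fs))
        rows.append(
            {
                "start_s": t0,
                "end_s": t0 + seg.duration_s,
                "start_idx": i0,
                "end_idx": i0 + n,
                "stage_id": seg.stage,
                "regime": seg.regime,
                "target_volume_ml": seg.target_volume_ml,
            }
        )
        t0 += seg.duration_s
        i0 += n
    return pd.DataFrame(rows)


def make_experiment(
    preset: str,
    seed: int = 0,
    cfg: SimConfig | None = None,
) -> tuple[WaveformRecord, pd.DataFrame]:
    """Generate a named experiment preset plus its stage annotations.

    Presets: ``baseline`` (stage 1 only), ``reversible_episode`` (one
    inflation–plateau–deflation cycle), ``terminal`` (stage-3 high plateau),
    ``full_timeline`` (all three stages in sequence).
    """
    plan = _preset_plan(preset)
    base = cfg if cfg is not None else SimConfig()
    base = replace(base, seed=seed, stage_plan=plan)
    record = generate(base)
    return record, annotations_for(plan, base.fs)
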