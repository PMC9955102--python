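# Methods

## Ordinal symbolization

A scalar series `x_1 … x_T` is embedded with dimension `m` and delay `τ`
(defaults `m = 6`, `τ = 1`): vector `j` is
`(x_j, x_{j+τ}, …, x_{j+(m−1)τ})`, giving `T − (m−1)τ` vectors. Each vector
is mapped to the permutation of `(1…m)` listing, in ascending value order,
the original 1-based positions of its elements: `(8, 9, 5) → 312`. This
mapping assumes only weak stationarity of the ordering statistics within a
window; no distributional assumptions are made.

Numerical choices, fixed once:

* **Ties** are broken earlier-index-first (a stable argsort). Ordinal methods
  formally assume continuously distributed data where ties have measure zero;
  on quantized monitor data the stable rule is deterministic and biases
  toward the ascending pattern only at the quantization scale.
* **Pattern ranking** is strict lexicographic via the Lehmer code:
  `rank(12…m) = 1`, `rank(m…21) = m!`. The rank is a bijection, so entropy
  and missing-pattern counts are independent of it; it matters only for
  naming `p(s_1)` (ascending) and `p(s_{m!})` (descending). Published
  listings of the `m = 3` alphabet sometimes order the interior patterns
  differently; any such order that keeps ascending first and descending last
  yields identical analyses.
* `m` is capped at 10 (`10! ≈ 3.6·10^6` counts per window is the tractable
  ceiling); `0 · ln 0 := 0`; natural logarithms throughout.

Permutation entropy is the Shannon entropy of the window's pattern
frequencies normalized by `ln m!`, so `H = 0` for any strictly monotone
segment and `H = 1` for uniform pattern usage. The missing-pattern count is
the number of patterns with zero occurrences, normalized by `m!` to `[0, 1]`.
With the default window of `3600 = 5·6!` samples a window holds 3595 vectors,
about 5 per pattern — enough for the coarse features used here (entropy,
missing fraction, the two extreme-pattern probabilities), not for resolving
individual interior-pattern probabilities.

## Filtering

ICP monitors sample at 200 Hz and pick up powerline interference. The
cleaning chain is an order-4 Butterworth band-stop and an order-4 Butterworth
low-pass at 60 Hz, in that order. The band-stop is specified by its 50 Hz
center; the edges (±2 Hz, a conventional notch width) are configurable. Both
filters run forward–backward (`sosfiltfilt`): zero phase keeps window
statistics aligned with the raw signal at the cost of doubling the effective
order. The low-pass cutoff must lie below Nyquist, so 200 Hz input is
required for the default bands.

## Sliding-window track

Windows are 0-based half-open `[start, start + 3600)` advanced by 1000
samples (18 s windows, 5 s steps at 200 Hz); a trailing partial window is
dropped. The series is symbolized once and each window tabulates the
contiguous slice of pattern ranks starting inside it. `mean_icp` is the mean
of the signal actually analyzed — the CLI filters first, so its reported
means are filtered means; pass an unfiltered record to `analyze` for raw
means. `sweep_m` follows the standard recommendation of exploring
`m = 3…7` with windows of `5·m!` samples (non-overlapping), which is how the
default `m = 6` / 3600-sample configuration is justified: `m = 7` needs
5040-pattern tabulations and 25 200-sample windows for the same coverage.

## Compliance

Intracranial compliance `ICC = dV/dICP` (mL/mmHg) is estimated by finite
differences of successive window means of volume and ICP, on the same window
grid as the complexity track. Window-mean differencing suppresses pulse-level
fluctuation; the estimate is undefined (NaN, never ±inf) for the first window
and wherever `|dICP| < 0.1 mmHg` (the default degeneracy guard, below which
the quotient is dominated by noise). On a noise-free exponential
pressure–volume law the estimator matches the closed-form derivative within
the discretization error of one window step.

## Stage rules

The classifier is a fixed-order rule table over `(PE, nNMP, p_first,
p_last)`: injury-free requires `PE > 0.3`, `nNMP < 0.90` and ascending-pattern
dominance; terminal requires `nNMP ≥ 0.95` and descending dominance;
`0.90 ≤ nNMP < 0.95` is intermediate; anything else is explicitly
indeterminate, because the three rules are neither exhaustive nor mutually
exclusive (a monotone artifact, for instance, has `nNMP ≈ 1` with ascending
dominance and matches no rule). Boundary semantics follow the inequalities as
stated: `nNMP = 0.90` is intermediate, `nNMP = 0.95` terminal-eligible. The
features deliberately exclude absolute ICP, so labels are invariant to
rescaling of the pressure channel. The thresholds are proof-of-concept
values, exposed for configuration, not validated cut-offs.

## Synthetic experiment generator

The generator emulates a porcine balloon-inflation experiment:

```
ICP(t) = p0 + p1·exp(E·V(t)) + pulse(t) + noise(t) + powerline(t)
```

* **Pressure–volume law**: exponential with elastance `E = 0.3 /mL`,
  `p0 = 2`, `p1 = 3` mmHg — a Monro–Kellie-consistent monotone convex curve
  giving 5 mmHg at empty balloon and ≈ 26 mmHg at 7 mL. The law is a modeling
  choice for emulation, not a measured curve.
* **Volume protocol**: piecewise linear; inflation at 2 mL/min (pump-driven,
  a free choice), deflation at 1 mL/min, holds at each segment target.
* **Cardiac pulse**: a phase-warped sinusoid (`sin(φ + β sin φ)`) with two
  harmonics, fundamental 1.8 Hz, half-amplitude 2 mmHg growing with mean ICP,
  amplitude-modulated by 0.25 Hz respiration. The warp sign flips with a
  severity index (0 at baseline mean ICP, 1 at 25 mmHg): at baseline the
  rising limb is the longer one, under hypertension the upstroke sharpens and
  the decay lengthens. This is the mechanism that reverses
  `p(ascending)` vs `p(descending)` between healthy and hypertensive windows.
* **Loss of complexity**: heart-period jitter, beat-amplitude jitter, and
  band-limited physiologic noise (SD 0.3 mmHg at baseline, low-passed at
  3 Hz, plus a small broadband floor) are all scaled by
  `c = 1 − coupling·severity` with `coupling = 0.8`; stage-3 segments force
  `c` to 0.02, producing the near-periodic terminal waveform. Scaling the
  noise floor together with the jitter is required for the terminal
  low-variability regime; a constant broadband floor would dominate the
  ordinal statistics of the smooth terminal signal.
* **Powerline**: a 0.2 mmHg, 50 Hz tone, so the notch filter is exercised
  end-to-end.

All randomness flows from one `numpy` generator seeded by the config; equal
seeds give bit-identical recordings. The morphology constants (warp ±0.6/
+0.55, harmonic weights 0.22/0.10, jitter coefficients) were calibrated once
so that the default rule thresholds separate the three simulated regimes on
default seeds, and then frozen.

**What the generator does not emulate**: arterial-pressure coupling and
autoregulation dynamics, Lundberg A/B waves, measurement drift and motion
artifacts, P1/P2/P3 ratio inversion as a distinct phenomenon, and
beat-morphology variability beyond amplitude/period jitter. Passing
end-to-end tests therefore demonstrates that the pipeline recovers the
constructed complexity orderings, not that the thresholds generalize to
animal or patient data.

## Problem sizes

The test suite and reference script run on deliberately modest sizes: the
end-to-end timeline is 1530 s at 200 Hz (306 000 samples, ≈ 300 windows,
about 10–45 windows per annotated segment), entropy-convergence checks use
200 000 i.i.d. samples at `m = 3`, and the exhaustive symbolization check
enumerates all 4-letter integer series up to length 8 for `m ∈ {2, 3}`.

## Known limitations

* Missing-pattern counts at `m = 6` depend on window length (3595 vectors
  cannot cover 720 patterns more than ~5× over); nNMP values are therefore
  only comparable between equal-length windows.
* The compliance estimator needs a volume channel; it is a surrogate for the
  clinical setting, where volume is not measured and nNMP itself is the
  candidate compliance proxy.
* CSV I/O assumes a uniform sampling grid; recordings with gaps must be
  segmented upstream.
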