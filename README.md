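# ordicp — ordinal-pattern complexity monitoring of ICP waveforms

`ordicp` analyzes intracranial-pressure (ICP) waveforms with ordinal-pattern
(Bandt–Pompe) statistics, for neurocritical-care researchers who want more out
of a 200 Hz ICP channel than its mean value. Continuous ICP monitoring guides
treatment of brain-injured patients, but the waveform itself carries
information about intracranial compliance — the ability of the cranio-spinal
system to buffer added volume — that a single pressure number hides. The
loss-of-complexity hypothesis predicts that as compliance is exhausted, the
waveform becomes simpler and more stereotyped; ordinal statistics quantify
exactly that.

## The statistics

Each embedded vector `(x_t, x_{t+τ}, …, x_{t+(m−1)τ})` of the signal is mapped
to the permutation `s_i` describing the ordering of its values (ties broken by
earlier index). With embedding dimension `m` there are `N = m!` possible
patterns; the empirical probabilities `P = (p_1, …, p_N)` over a window give

* **permutation entropy** `H[P] = −Σ p_i ln p_i / ln N  ∈ [0, 1]`,
* the **number of missing patterns** (NMP): patterns with `p_i = 0`,
  normalized by `m!`,
* `p(s_1)` and `p(s_{m!})`: probabilities of the fully ascending and fully
  descending patterns (ranked lexicographically, ascending first).

Computed in sliding windows (default: 3600 samples = `5·6!`, shifted by 1000,
with `m = 6`, `τ = 1`), these form a monitoring track alongside window-mean
ICP and — when a balloon-volume channel is present — windowed intracranial
compliance `ICC = dV/dICP`. A three-stage rule classifier summarizes each
window: **injury-free** (PE > 0.3, nNMP < 90%, `p(s_1) > p(s_720)`),
**terminal** (nNMP ≥ 95%, `p(s_720) > p(s_1)`), **intermediate**
(nNMP in 90–95%), else **indeterminate**.

Because real porcine balloon-inflation recordings are not redistributable, the
package ships a synthetic generator (`ordicp.simulate`) that emulates the
three experimental stages — baseline near 5 mmHg, reversible hypertension
episodes driven by a balloon protocol through an exponential pressure–volume
relation, and a terminal near-periodic high-ICP stage — including 50 Hz
powerline contamination to exercise the filtering chain (order-4 Butterworth
notch at 50 Hz, then order-4 low-pass at 60 Hz, zero-phase).

## Worked example

```python
>>> from ordicp import (EmbeddingConfig, symbolize, distribution,
...                     permutation_entropy, missing_patterns)
>>> ranks = symbolize([3, 6, 8, 9, 5, 10, 2], EmbeddingConfig(m=3, tau=1))
>>> ranks
array([1, 1, 5, 3, 5])
>>> dist = distribution(ranks, m=3)
>>> dist.probs
array([0.4, 0. , 0.2, 0. , 0.4, 0. ])
>>> round(permutation_entropy(dist), 5)
0.58876
>>> missing_patterns(dist)
(3, 0.5)
```

The seven samples yield five embedded vectors mapping to the patterns
`123, 123, 312, 213, 312` (lexicographic ranks 1, 1, 5, 3, 5): the ascending
pattern and pattern `312` each occur with probability 0.4, pattern `213` with
0.2. Three of the six `m = 3` patterns (`132`, `231`, `321`) never occur, so
the missing-pattern count is 3 (normalized 0.5), and the entropy of the
three-point distribution is `−(2·0.4 ln 0.4 + 0.2 ln 0.2)/ln 6 ≈ 0.589`.

## Command line

```sh
ordicp simulate --preset full_timeline --seed 1 --out ft.csv
ordicp analyze  --input ft.csv      --output ft_track.csv
ordicp classify --input ft_track.csv --output ft_cls.csv
ordicp report   --input ft_cls.csv  --outdir ft_rep
```

prints the per-stage summary (plus ICP/PE and ICP/nNMP overlay figures and an
nNMP box plot):

```
  stage_label  n_windows  median_pe  median_nmp_norm  median_mean_icp_mmhg
indeterminate         56   0.288016         0.760417             15.426176
  injury_free        104   0.449638         0.682639              5.763159
 intermediate         50   0.167857         0.925000             26.521385
     terminal         93   0.160085         0.959722             34.183031
```

Healthy baseline windows show high entropy and moderate missing-pattern
fractions; hypertension-plateau windows drop to low PE with nNMP in the
intermediate band; terminal windows are the most stereotyped (nNMP ≈ 0.96)
with the descending pattern dominant. Indeterminate windows sit on the
inflation/deflation transitions.

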