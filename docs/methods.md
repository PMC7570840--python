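# Methods

## The recognition problem

A gasbag tactile sensor pressed against plants while moving at field
speed produces, per contact, a voltage time series from an internal air
pressure sensor. Four contact classes occur: a weed canopy brushing the
bag (A), and a rice stem touching the end (B), middle (C) or root (D)
of the bag. The task is binary — weed (A) versus rice (B∪C∪D) — but
per-type accounting is kept throughout because the three rice contact
geometries behave very differently.

## Synthetic signals

No recordings from the original experiment are available, so
`ricetact.signals` generates signals whose *feature statistics* emulate
the published per-class means; waveform shape is not a calibration
target. Each signal is

```
x(t) = baseline + jitter + noise(t) + sweep(t) + slips(t)
```

* **baseline** — class resting voltage near 4.5 V, plus a per-contact
  Gaussian jitter (σ = 2 mV for all classes). The jitter reflects the
  sensor re-settling between contacts; it also means the per-signal mean
  alone cannot separate A from B, consistent with the published tables
  in which the two classes are dimensionally almost identical.
* **noise** — fractional Gaussian noise (Davies–Harte circulant
  embedding) scaled to the class's noise amplitude (0.75–1.3 mV).
  Micro-vibrations during sliding friction are strongly persistent;
  class Hurst targets are 0.92 (A, C, D) and 0.65 (B).
* **sweep** — a random-phase, ~2.5-cycle low-frequency oscillation
  (4.5–4.6 mV) present only for C and D: the bag wraps around the stem
  and springs back, a deformation an order of magnitude larger than the
  friction noise. The sweep gives C/D their ~10× variance, ~2.5× peak-to-
  peak and sub-Gaussian kurtosis (≈1.7–1.8, a sinusoid-dominated trace),
  and pushes the finite-sample R/S slope slightly above 1, as the
  published rice-class estimates show.
* **slips** — a sparse Poisson train (1.1 events/100 samples for B) of
  sharp-onset, exponentially decaying impulses (1.9 mV nominal, ±50%
  size spread). Stick–slip releases at the gasbag end make B
  leptokurtic (mean kurtosis ≈ 4, against ≈ 3 for A's Gaussian noise)
  without materially moving its variance or peak-to-peak away from A's.

Signal length defaults to n = 1024 samples: long enough for stable R/S
and box-counting estimates, small enough that the full 1800-signal
protocol runs in seconds. Per-signal RNG streams are derived from
`(master seed, class, index)`, so changing one class's allocation never
shifts another class's draws.

**Calibration targets.** With the default presets and ≥200 signals per
class: variance(C), variance(D) > 5×variance(A); peak-to-peak(C, D) ≈
2–2.5× A; kurtosis ordering B > A > D > C; R/S estimates C, D > A > B;
and classes A vs C∪D separated by ≥3 pooled standard deviations on at
least one feature. The B-class Hurst target (0.65) is deliberately
lower than the published B estimate (0.94): with only interval-scale
calibration available, the fractal separation between A and B carries
the information that, in the real data, many features contribute
jointly; the published *ordering* (C, D > A > B) is preserved. What the
generator does **not** emulate: amplitude drift within a contact,
sensor quantisation, field-speed variation, inter-plant variability
beyond the per-contact jitter, or any dependence between consecutive
contacts. Passing tests therefore demonstrate that the pipeline's
machinery is correct and self-consistent, not that field accuracy would
match.

## Features

Population (1/n) moment conventions throughout, exactly as the
formulas print: variance and standard deviation use 1/n, kurtosis is
the biased non-excess fourth standardised moment (Gaussian → 3),
skewness the biased third. The identity `variance = std²` holds exactly
(variance is stored as the square of the computed standard deviation);
`RMS² = mean² + variance` holds to 10⁻¹² relative.

The amplitude numerator of the pulse, peak and margin factors is the
**peak-to-peak** value rather than max(x): on near-constant positive
traces (≈4.5 V with millivolt fluctuations), max(x)/μ is pinned at
1.000… and carries no information, while PK/μ reproduces the published
order of magnitude (≈1.5×10⁻³) and the published near-equality of the
pulse, peak and margin factors. A literal `peak_mode="max"` is
available. The margin (clearance) factor uses the standard form
PK/((1/n Σ√|xᵢ|)²).

**Box dimension** — the graph is normalised to the unit square; for
each dyadic box size δ = 2⁻ᵏ, k = 2…7, occupied boxes are counted
column-wise (⌈span/δ⌉ per time column, at least 1), and the dimension
is the slope of ln N on ln (1/δ). A smooth curve gives 1, a Brownian
graph 1.5, an fBm graph ≈ 2 − H. Column-span counting undercounts
slightly at coarse scales; recovery is within ±0.15 of 2 − H for
H ∈ {0.3, …, 0.9} at n = 4096.

**Hurst exponent** — classic rescaled range: dyadic windows 8…n/4
(extended to n/2 when fewer than four fit), ⌊n/N⌋ blocks per window,
R/S averaged over blocks with zero-variance blocks skipped, slope of
log₁₀(R/S) on log₁₀ N. The estimator carries the well-known
finite-sample bias (≈+0.09 at H = 0.3, ≈−0.06 at H = 0.9 for n = 4096)
and can exceed 1 on strongly persistent signals, as the published
rice-class values do; no bias correction is applied because the plain
regression slope is the definition in use.

## GA feature selection

The fitness of a mask is the prior-weighted within-class scatter plus
between-mean displacement over the selected columns — algebraically
identical both to the average pairwise squared distance between samples
(the test oracle, checked to 10⁻⁹ relative) and, by the ANOVA
decomposition, to the **total variance** of the selected columns. Two
consequences are documented rather than hidden:

* The criterion is scale-sensitive: columns are used raw, so features
  with large numeric spread (kurtosis, skewness, the fractal pair)
  dominate, and near-constant columns (waveform factor, variance in
  volts²) are invisible to it.
* The criterion is monotone under mask growth — adding any column can
  only increase fitness — so the elite chromosome drifts toward the
  full mask. Frequency-of-occurrence counting is therefore done on each
  generation's *champion*, ranked with a parsimony margin: a feature
  must contribute more than 0.1% of the best raw fitness
  (`GAConfig.champion_parsimony`) to justify its place. This
  implements the subset-selection intent (d < D) without constraining
  evolution itself: roulette selection, the elite and the monotone
  best-fitness trajectory all use the raw criterion. On a planted
  dataset the champion counts separate informative from noise features
  cleanly (noise counts 0–700 out of 2500, informative saturated),
  matching the published pattern of occurrence counts.

GA defaults are the study's settings: crossover 0.8, per-bit mutation
0.01, population 500, 500 generations, five repeated runs aggregated by
summed frequency, top-5 kept, ties broken in letter order. Empty masks
are repaired by setting one random bit; elitism is 1.

## Classifier

Three layers, sigmoid activations, one-hot targets, MSE loss,
full-batch gradient descent. The hidden width must satisfy
D ≥ 2M + 1 for M inputs (default 12, which admits up to five features;
the six-feature dimensionless group gets the minimal admissible 13).
Unstated training details follow the classic momentum + adaptive-rate
recipe: momentum 0.9 over the previous accepted step; learning rate
×1.05 after an improving epoch; on an epoch worsening the error by more
than 4% the step is rejected, the momentum memory cleared and the rate
×0.7. Initial weights are seeded uniform(−0.5, 0.5)/√fan-in, biases
zero. Training stops at MSE ≤ 10⁻³ or 5000 epochs. Inputs are z-scored
on training statistics — the raw features span ~10 orders of magnitude
(variance ~10⁻⁶ V² against a ~4.5 V mean), so unscaled training would
stall. Analytic gradients agree with central finite differences to
10⁻⁶ relative.

## Evaluation protocol

Training uses 300 signals per class (1200 total); three 200-signal
testing sets use allocations (50/50/50/50), (57/43/50/50) and
(43/57/50/50) for A–D. Weed accuracy is the type-A correct fraction;
rice accuracy pools B, C, D. Table accuracies are rounded to one
decimal, case recognition rates to two — reproducing every published
percentage from the published per-type counts is an exact-arithmetic
test of this module. The physical contact-position experiment (rail,
trays, 150 plants per case) is replaced by a simulated analogue: 150
fresh rice signals of the case's type (I→B, II→C, III→D) classified by
the trained model. The published field rates (90.67/98/96%) are
context, not targets; on synthetic data the simulated rates are
substantially higher because the generator's class separations are
cleaner than field conditions.

## Numerical and degenerate-input choices

* Constant signals: variance/std/PK are 0, waveform factor 1, the
  PK-numerator factors 0; standardised moments are returned as 0 (their
  symmetric limits). Zero-mean or zero-RMS signals raise errors for the
  normalised factors.
* Box counting requires ≥64 samples and ≥4 scales spanning ≥2 octaves;
  R/S requires ≥4 usable window sizes (all-constant blocks drop a
  scale).
* Davies–Harte eigenvalues are clipped at zero (tiny negative values
  arise from truncation for H near 1).
* Roulette selection falls back to uniform when total fitness is 0.
* Z-score scales of constant feature columns are set to 1.

## Problem sizes

Default experiment sizes — n = 1024 samples per signal, 1800 signals
per full protocol run, 20 replicates per fractal-recovery setting,
planted-GA tables of 400×13 — keep a full pipeline run (generation →
features → GA → four networks → case experiment) around 20–30 s on one
CPU while leaving all statistical margins comfortable.

## Known limitations

* The generator is calibrated to first- and second-order feature
  statistics and orderings, not to waveforms; cross-feature
  correlations in real contacts are not modelled.
* The published tables mix per-class means of per-signal features, so
  cross-table identities (e.g. recomputing the mean waveform factor
  from mean RMS and mean voltage) hold only approximately and are not
  asserted.
* The scatter criterion measures spread, not class separation per se;
  its published use is reproduced faithfully, including that quirk.
* R/S and box-counting estimates are biased at these signal lengths;
  parameter-recovery tolerances (±0.1, ±0.15) reflect that.
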