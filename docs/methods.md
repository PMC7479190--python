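# Methods

This note documents the statistical model behind `phasetrans`, the
parameter choices, the numerical conventions, and what the synthetic
benchmarks do and do not demonstrate.

## The detection problem

A *phase transition* in a monitored system is a discontinuous
reorganization of its dynamics driven by a drifting control parameter. In
short behavioural time series (80–300 points, daily sampling, coarse rating
scales, substantial noise) such transitions rarely announce themselves as a
clean step in the mean: the change may live in variability, frequency
content, ordinal structure, recurrence geometry, or inter-variable
coherence. No single statistic is sensitive to all of these, and at these
lengths every statistic has a non-trivial false-alarm rate. The design
principle of the package is therefore *convergent validation*: run many
weakly coupled detectors, demand that their change points cluster, and test
the clustering against a random-scatter null.

## Change-point analysis

For a candidate split of x (length N) into x₁ = x[1..b−1] and x₂ = x[b..N],
a change point is accepted when C(x₁) + C(x₂) + k < C(x).

* Mean statistic: C(x) = N·var(x), with the *sample* variance
  (denominator N−1) — this convention is forced by the worked example
  {2,2,2,4,…,4}, whose segment costs are 0, 4 and 9.33 only under ddof = 1.
  A singleton segment costs 0.
* Variance statistic: C(x) = N·ln(max(var(x), 1e−12)), the Gaussian
  log-likelihood cost that is standard for variance shifts. The floor keeps
  exactly-constant segments finite; the penalty applies on this log scale
  unchanged.

The scan is exhaustive over all admissible splits (both segments at least
`min_segment = 2` points), vectorized with prefix sums; ties break toward
the smallest index, and the reported index is the first point of the *new*
segment (1-based), so the worked example reads "4". At most one mean and one
variance point are detected per series; the variance pass needs no separate
centering because variance is invariant to a per-segment mean shift.

The default penalty k = 1 is deliberately permissive: on ~300 points of
unit-variance i.i.d. noise the best split improves the cost by ~6–12, so a
*single* CPA pass detects something almost always (measured 94.5%
mean-statistic detection rate at N = 200; 27% at k = 5, 0% at k = 15).
Specificity is not supposed to come from one pass — it comes from the
convergence layer: under the no-transition null the per-row detections
scatter, the pooled dispersion matches the uniform surrogates, and the
verdict is negative. Users who want conservative single-series CPA should
raise `penalty`.

## First-order indicators

All indicators use trailing windows: the value computed from observations
t−w+1..t is assigned to time t (the only alignment usable prospectively),
and a derived value at position i maps back to original time
offset + i − 1 with offset = t0 + w − 1.

**Dynamic complexity** (window 7). The fluctuation measure partitions the
window into maximal monotone runs (plateaus extend the current run); each
run contributes |Δvalue|/Δtime, and the sum is normalized by
(hi−lo)·(m−1), the value of a full-range alternation. The distribution
measure compares the sorted window against the ideal uniform grid over
[lo, hi]: D = max(0, 1 − Σ|y(i) − g_i| / (m(hi−lo)/2)). Both lie in [0, 1];
DC = F·D. These concrete operationalizations satisfy the defining
qualitative requirements (F = 1 for extreme alternation, 0 for constancy;
D = 1 for even spread, 0 for a degenerate pile-up at one end) — other
normalizations exist in the literature, and this choice is fixed here and
exposed through `ScaleRange`. By default the range is the observed global
min/max of the (z-scored) series; rating-scale bounds can be supplied
instead. Out-of-range values are clipped rather than rejected, which keeps
noise-added simulations usable.

**Permutation entropy** (window 7, word length 3). Each window's
w−n+1 = 5 words are recoded to ordinal patterns; ties are broken by order
of occurrence (earlier index → lower rank), which matters for coarse rating
data. H = −Σ p ln p / ln(n!) ∈ [0, 1]. Note that a width-7 window cannot
reach H = 1 with n = 3 (5 words cannot cover 6 patterns); this is a
property of the parameters, not a defect.

**Stockwell transform and instantaneous frequency.** The S-transform is
computed in the frequency domain: for voice n = 1..⌊N/2⌋,
S[τ,n] = IFFT_m(X[(m+n) mod N] · exp(−2π²m²/n²)), with X the DFT of the
mean-removed signal and the Gaussian evaluated at circularly wrapped signed
offsets m ∈ [−N/2, N/2) so each voice window is symmetric about its center
frequency. The zero-frequency row carries the series mean and is excluded
from the IF moment. IF(τ) uses power weighting (amplitude²), the standard
spectral-moment definition, and always lies in [0, 0.5] cycles/sample.

One consequence worth knowing: the S-transform's voice bandwidth grows
proportionally to frequency, so for white noise the per-voice power rises
~linearly with f and the time-averaged IF sits near ∫f²df/∫f df = 1/3
(measured 0.317), *not* at the flat-spectrum midpoint 0.25 that a
constant-bandwidth spectrogram would give. IF values are comparable across
time within a series, which is all the change-point layer needs.

**Synchronization.** Mean absolute pairwise Pearson correlation in a
7-point trailing window. Pairs with a flat column in the window are
excluded rather than scored 0 (an arbitrary constant would bias coherence
downward on coarse data); windows with fewer than two live columns are
undefined (NaN) and skipped by the second-order layer together with their
time stamps. SPA needs the system's component variables; for a univariate
input the SPA rows are simply absent from the report.

**Recurrence.** Time-delay embedding with dimension 3, delay 1; Euclidean
distance matrix, unthresholded (binarizing would add an undocumented radius
parameter). For quantification, each *row* of the matrix is scanned by CPA;
detected column indices are pooled per statistic, rows without a detection
are skipped (not counted as zeros), and the rounded arithmetic mean is
reported as the plot's change point, mapped to original time through the
first embedding coordinate.

## Second-order layer and report

CPA runs on the z-scored original series, on every indicator, and on each
indicator's moving average and moving variance (window 20; 5 for IF, whose
sampling is already effectively smoothed). Indicator rows are scanned on
their *natural* scale, not re-standardized: the fixed penalty then acts as
an effect-size filter for the mean statistic on [0,1]-valued indicators
(flat, uninformative rows produce no mean detection), while the variance
statistic is scale-free by construction. Re-standardizing every row would
make the mean statistic fire on essentially every ~300-point row and was
also measurably worse at recovering known transition windows.

The time-frequency matrix itself contributes no row — it is a picture, not
a series — it enters only through IF.

All detections are pooled flat (a row with nothing contributes nothing);
the report carries per-row points, the pooled list, its mean and sample SD,
and the two surrogate tests. `oversampling_variant` re-pools without the
MA/MV rows, which re-analyze the same indicators and could oversample one
transition; on the Hénon benchmark the verdict survives this exclusion.

## Surrogate dispersion tests

The null model draws 100 sets of as many integers as there are pooled
points, uniformly with replacement on {1..N}. Two dispersion statistics are
computed for the real pool and every surrogate set: IQR/N·100 (quartiles by
linear interpolation) and sample SD/N·100 (the σ of a fitted normal; the
n−1 convention differs from the ML fit only by that factor). The 95%
interval is the percentile interval of the surrogate values — the only
construction requiring no distributional assumption. A transition verdict
requires *both* statistics outside their intervals (below, for clustering).
Calibration, measured: uniformly scattered "real" points are flagged by at
least one test in 10.2% of 500 replicates; the full pipeline on no-shift
noise controls rejects (both tests) in 12% of 100 seeded runs. Duplicate
points within a surrogate set are allowed, as a plain uniform generator
produces them.

## Synthetic benchmarks

**Hénon ramp.** x_{k+1} = y_k + 1 − a·x_k², y_{k+1} = 0.3·x_k from
x₀ = y₀ = 0; a = 1.20 for iterations 1–124, ramped by 0.002 per step over
iterations 125–150 to 1.25 (reaching it at 150), constant thereafter; 300
points total, the initial condition excluded. The orbit moves from chaos to
a period-7 rhythm. This is the package's primary end-to-end benchmark: the
pooled change points must cluster (dispersion far below the random bounds)
with their mean in or near the ramp window.

**Stochastic regime shifts.** A seeded generator ramps chosen parameters
linearly across a transition window (default [150, 160] of 300 points) on a
baseline of unit-variance Gaussian white noise, with effects expressed
relative to that baseline: mean shift 3 noise-SDs; noise-SD ratio 4;
sinusoid of amplitude 2 with frequency ramped 0.05 → 0.20 cycles/sample
(constant mean and variance — the transition type plain CPA cannot see);
AR(1) coefficient 0 → 0.8 with variance-stabilized innovations (only the
autocorrelation changes). A multivariate variant mixes each component with
a shared latent factor whose loading ramps 0 → 0.8, producing the rising
coherence probed by SPA. These defaults are fixed study conditions, chosen
as large-but-plausible effects for daily-rating data.

What the generator does *not* emulate: bounded discrete rating scales,
missing days, slow trends, seasonal structure, or the feedback between
control parameters and order parameters that characterizes self-organizing
systems. Passing benchmarks therefore demonstrate correct mechanics and
reasonable sensitivity under idealized noise, not clinical validity.

**Recovery accuracy.** On composite transitions that shift mean, variance
and frequency together — the archetype of a qualitative regime change, and
the analog of the chaos→rhythm benchmark — the median error of the pooled
mean against the true window midpoint is ~7 samples over 20 seeds. On
*single-feature* shifts the error is larger (median ~17 samples for a pure
mean step, more for frequency-only): most indicator rows are then
uninformative by construction, yet the permissive penalty makes them emit
false detections, and because all indicators are computed from the same
noise realization those false detections are correlated across rows and do
not average out. This is a known property of flat pooling; weighting rows
by informativeness would change the method and is deliberately not done.

## Numerical conventions and degenerate inputs

- Sample statistics use ddof = 1 throughout (z-transform, costs, moving
  variance, pooled SD, σ%).
- Time indices are 1-based; a change point marks the first index of the new
  segment.
- Pooled RP means are rounded with `np.rint` (ties to even; exact .5 ties
  are measure-zero in practice).
- A constant input series yields an empty report flagged "no transition
  detected" (the z-transform itself, called directly, raises on zero
  variance, as do DC/PE on windows shorter than configured).
- A pool with a single point reports SD 0 with a `single_point` flag and no
  surrogate test (dispersion of one point is undefined).
- The pipeline requires N ≥ 40 so that every window chain
  (indicator 7 → smoothing 20) fits with room for the split scan.
- Seeds: the surrogate draws and the regime-shift generator are the only
  random elements; both take explicit integer seeds and are bit-reproducible.
  The Hénon orbit and the pipeline itself are deterministic.

## Known limitations

- Exactly one change point per statistic per row: staged or multiple
  transitions produce a compromise pooled estimate.
- The permissive default penalty makes single rows unreliable in isolation;
  only the pooled, surrogate-tested verdict is meant to be interpreted.
- The IF of short windows near the series edges is biased by the circular
  FFT; downstream CPA tolerates this, but pointwise IF values within ~10
  samples of either edge should not be over-read.
- Dispersion tests assume the pooled points are exchangeable; rows are
  correlated (they share the source series), so the effective sample size
  of the pool is smaller than its count. The null calibration above shows
  the practical false-positive rate stays near the nominal level under
  these defaults.
- No missing-data handling: ingestion expects complete, equidistant series.
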