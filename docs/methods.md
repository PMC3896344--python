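# Methods

This note documents the models, defaults and numerical choices behind
`spikedwt`, and what its synthetic-data checks do and do not establish.

## Rate estimation

A trial's spike train is treated as a sum of delta functions and convolved
with a unit-area Hanning kernel

w(t) = (1/L)·0.5·(1 + cos(πt/L)),  |t| ≤ L,

with half width L = 50 ms by default. "Half width" is read as half the
kernel *support* (total support 2L), not FWHM; the reading is configurable
through the `halfwidth_ms` parameter. The continuous-limit peak of the
unit-area kernel is 1/L (20 Hz per spike at the default).

The dense rate is evaluated on a midpoint grid over the analysis window.
The requested grid step (default 1 ms) is snapped to the nearest exact
divisor of the bin width — 10.9375/11 ≈ 0.994 ms at the defaults — so that
every bin averages the same integer number of dense samples. The kernel is
evaluated *exactly* at each spike's offsets and renormalized per spike so
its discrete integral is exactly one. This choice makes two properties hold
simultaneously: mass conservation (the discrete integral of the dense rate
equals the number of spikes whose kernels lie inside the evaluated span, to
float precision) and stability under grid refinement (halving the step
changes bin values only at the midpoint-rule error, O(h²) ≈ 10⁻⁴ relative).
An earlier histogram-then-convolve formulation quantizes spike times to the
grid and fails the second property at the ~1% level.

Convolution precedes windowing: spikes outside the analysis window
contribute through their kernel tails, so window edges reflect the actual
recording rather than zero padding. Window bins are half-open, 1-indexed,
of width T/N (T = 1.4 s, N = 128 by default; N must be a power of two
divisible by 2^levels). The control window is the T immediately preceding
stimulus onset.

Note one smoothing caveat: a periodic spike train at inter-spike interval
d produces a *flat* rate only when d = 2L/k for integer k ≥ 2 (the raised
cosine's partition-of-unity condition); at d = 2L the smoothed rate
oscillates over its full range. The default L = 50 ms therefore resolves —
rather than flattens — rhythmic firing slower than 20 Hz, which is what a
time-frequency analysis wants.

## Wavelet power maps

The binned vector is decomposed with PyWavelets (`wavedec`, `db1`,
`mode="periodization"`, 4 levels). With the orthonormal Haar convention
(detail (a−b)/√2, approximation (a+b)/√2 per pair) the squared coefficient
is the signal power in its cell and total power equals the energy of the
binned vector (Parseval); the filter has length 2 and the lengths are
dyadic, so no boundary extension is ever touched and the extension mode is
irrelevant. The test suite verifies the transform against an explicit
128×128 orthonormal Haar matrix built independently of PyWavelets.

Coefficients are indexed 1-based in natural time order. Level j
(j = 1…levels) holds N/2ʲ details; the approximation is reported as level
levels+1 with N/2^levels coefficients. The time window of (level, index)
is ((index−1)·T/n_level, index·T/n_level); windows tile [0, T] exactly per
level. Frequency bands derive from the binned-rate Nyquist frequency
f_N = N/(2T) = 45.714… Hz: level j spans (f_N/2ʲ, f_N/2ʲ⁻¹), the
approximation (0, f_N/2^levels). Band edges are exact internally and
rounded to two decimals for display (45.71, 22.86, 11.43, 5.71, 2.86).
Other wavelet kernels are accepted for exploration, but the
coefficient-to-window mapping is exact only for db1; for longer filters
the windows are nominal.

## Group comparison

The sample unit is the single trial, pooled across all neurons of a
subset; comparisons are performed only within subsets defined by metadata
(response type × morphological type by default), since pooling across
heterogeneous response classes would mix opposite-signed effects.

Each coefficient is tested with a two-sided Mann-Whitney U. Exact
enumeration is used when the pooled sample has ≤ 16 tie-free observations;
otherwise the tie-corrected normal approximation with continuity
correction. Ties are common here — empty windows give exact zero powers —
and a coefficient whose values are identical across all trials is
degenerate: p = 1, U = n₁n₂/2.

The FDR family is the complete coefficient set (128 at defaults) of one
(subset, comparison, period). The Benjamini-Hochberg step-up finds the
largest k with p₍ₖ₎ ≤ k·q/m; `crit_p` is reported as the largest rejected
p-value, and the linear threshold k·q/m is reported alongside since both
conventions circulate. The per-coefficient *minimal rejecting q* is the BH
adjusted p-value rounded up to a 0.01 grid over (0, 0.25] — the
transparent reconstruction of batch re-runs at stepped q levels.

Tiers: **significant** = rejected at q = 0.10. **Marginal** = minimal
rejecting q strictly between 0.10 and 0.25, *and* the control-period
family has zero rejections at that same q, *and* the coefficient's window
is not fully contained in the union of significant-tier intervals (the
containment reading of "not already covered"). Direction is the sign of
median(A) − median(B). Merged intervals are the unions of the windows of
same-tier coefficients, touching intervals joined.

The label-shuffle control permutes condition labels over the pooled trials
of a subset and re-runs the full comparison per shuffle, reporting the
primary-tier rejection count; the permutation stream is seeded. A caution
that follows from FDR arithmetic: under an exchangeable null the
*probability of at least one rejection* in a 128-test family at q = 0.10
is ≈ q, so roughly one control family in ten will reject something.
"Clean control" is therefore a per-dataset diagnostic, not a guarantee,
and the calibration tests assert rates, never absolute zeros.

## PSTH baseline

Spike counts in half-open 50 ms bins (28 over the response window) are
compared bin by bin with exactly the same U-test/FDR machinery, including
the control-window condition for the marginal tier. Differences in outcome
between the PSTH and wavelet analyses therefore isolate the effect of the
representation: the wavelet analysis tests several timescales at once and
sums significant windows across levels, which on the synthetic latency
cohorts yields longer significant durations than the single-scale PSTH in
the majority of replicates.

## Spike detection

Voltage traces are optionally high-pass filtered (zero-phase second-order
Butterworth; default cutoff 100 Hz in the juxtacellular preset — the
filter order and cutoff are conventional spike-band choices and exposed as
configuration). The detection threshold is a fraction of the maximum peak
amplitude — 1/2 intracellular, 1/3 juxtacellular — measured from the
*median* of the processed trace, a robust baseline under slow drift (the
reference point is otherwise arbitrary and configurable, as is a per-trace
absolute threshold override). Each above-threshold excursion is refined to
its local maximum; lesser peaks within the refractory guard
(`min_separation_ms`, default 2 ms) of a larger accepted peak are then
suppressed in amplitude order. Amplitude-ordered suppression (rather than
first-come-in-time) makes the detected count provably non-increasing in
the threshold, which a time-greedy rule violates on noisy traces when a
raised threshold splits one excursion into two crossings. The guard
replaces manual curation of false positives; it is not a biophysical
claim. On noisy traces the reported time is the observed peak, which noise
can displace within the spike waveform (~1 ms for millisecond-wide
spikes); sub-sample accuracy is only meaningful for clean traces.

## Synthetic cohorts

The generator emulates single-trial antennal-lobe-like responses as
inhomogeneous Poisson processes with piecewise-constant rate envelopes:
a baseline rate, stimulus-locked phases, a per-condition onset latency
added to every phase boundary, and optional post-stimulus tails. Presets
(rates are illustrative, not estimates from recordings):

- biphasic: 5 Hz baseline; 30 Hz for 0–200 ms; 1 Hz for 200–500 ms;
- excited: 5 Hz baseline; 30 Hz for 0–500 ms;
- inhibited: 5 Hz baseline; 1 Hz for 0–500 ms;
- default onset latency 175 ms; the latency-coding study condition
  contrasts 175 vs 300 ms;
- stimulus duration 500 ms, so the 1.4 s response window extends 900 ms
  past offset; recording span −1.6 to +1.6 s around onset, covering the
  control window plus kernel margins.

Simulation is by thinning against the envelope maximum, exact for bounded
envelopes; per-trial generators derive from
`SeedSequence([cohort_seed, crc32(condition), trial_index])`, so every
sub-stream is reproducible in isolation. A dead-time parameter is
available but off by default — the analysis assumes nothing about
refractoriness.

What passing tests on these cohorts shows: correct FDR calibration under
exchangeability, correct localization of planted envelope differences, and
the wavelet/PSTH sensitivity ordering under Poisson variability. What they
do not show: robustness to non-Poisson spiking (bursting, adaptation),
across-neuron heterogeneity within a pooled subset, trial-to-trial gain
drift, or correlated noise — real recordings have all of these, and the
statistical guarantees there rest on the rank test's distribution-freeness
per coefficient, not on the generator.

## Problem sizes in the checks

The calibration suite uses 500 exchangeable replicates (20 vs 20 trials)
for the null rejection rate, 100 latency-contrast replicates for
localization and the wavelet-vs-PSTH comparison, 200 label shuffles on one
data set, and 1000 random vectors for the energy/reconstruction property;
the full suite runs in well under a minute on one core.

## Known limitations

- The coefficient time-window mapping assumes db1; other kernels get
  nominal windows only.
- Pooling trials across neurons treats neurons as exchangeable within a
  subset; strong per-neuron effects can dominate a comparison.
- The minimal-q grid scan reports values on a 0.01 grid; finer structure
  of the adjusted p-values is available programmatically (`bh_adjusted`).
- Detection offers no spike sorting; overlapping units must be separated
  upstream.
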