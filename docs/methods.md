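# Methods

This note documents the models, estimators and numerical choices behind
`whiskcode`, in the spirit of a methods section: what is computed, under
which assumptions, which knobs matter, and what the synthetic benchmark
does and does not establish.

## Signal chain and conventions

All analysis runs at 1 kHz.  The tracked whisker azimuth (degrees,
protraction = increasing angle) is low-pass filtered at 30 Hz with a
4-pole Butterworth applied forward and reverse — the two passes cancel
the phase response, so the effective amplitude gain is |H(f)|² of the
one-way filter — and then up-sampled to 1 kHz by polyphase resampling
(Kaiser window, β = 12; linear interpolation was rejected because its
spectral images leak into the 6–30 Hz whisking band, and the default
Kaiser β leaves ~0.8% passband ripple that breaks DC exactness).  The
**set point** is the < 6 Hz component of the filtered angle.  The
**phase** is the angle of the analytic (Hilbert) signal of the 6–30 Hz
band; for a protraction-positive trace this puts φ = 0 at protraction
maxima and ±π at retraction minima, and the convention is pinned by a
construction test on a synthetic whisk rather than trusted blindly,
because tracker angle polarity is site-specific.  The analytic-signal
magnitude serves as the whisking **amplitude envelope**.

Intervals are half-open `[start, end)` in seconds; all masks are derived
at 1 kHz.

## Epoch segmentation

No standard operational definition of whisking onset exists, so the
detector is a declared choice, parameterized in `SegmentationParams`:
samples with amplitude envelope ≥ 2.5° (i.e. ≥ 5° peak-to-peak, the
same floor that separates whisks from twitches) are active; gaps
< 250 ms are bridged; bout edges are extended outward to the 1° envelope
floor; candidates shorter than 500 ms are labeled `excluded`, as is any
supra-floor movement that never qualifies as whisking (this subsumes
single back-and-forth twitches below 5° peak-to-peak).  Excluded
episodes enter neither the quiet nor the whisking pool.  Treadmill
activity sustained ≥ 400 ms is overlaid as `locomotion`.  Quiet,
whisking and excluded intervals tile the recording exactly (asserted at
construction).

On generator sessions the detector recovers bout onsets with a mean
error of ~+6 ms and ~97–99% of onsets/offsets within ±40 ms; the
residual lag is the time the envelope needs to clear the floor on the
100 ms bout ramp.

**Rhythmic whisking** is the subset of whisking with envelope ≥ 2.5°
sustained ≥ 300 ms (≈ 3 cycles at 10 Hz), clipped 200 ms from the
recording edges (zero-phase filters are unreliable there); a cell is
eligible for phase analysis when it has > 20 s of rhythmic time.

## Spike statistics

The instantaneous rate is a centered 100 ms boxcar count at 1 ms steps;
a causal window would bias every latency estimate by +50 ms.  At the
recording edges the count is normalized by the covered window length.
Epoch rates are counts over duration; ISIs spanning an epoch boundary
are discarded rather than truncated (truncation manufactures short
ISIs).  The peri-CS histogram (±50 ms, 1 ms bins) validates sorting: the
pause is the longest empty run from lag 0, and ≥ 8 ms passes.

## Modulation tests

Rate modulation: two-sided Mann–Whitney on per-epoch rates (whisking vs
quiet), p < 0.05, direction from the median difference; identical
machinery applies to CS trains.  Under the generator's null (gain 0)
the measured rejection rate is 5–6% over 1500 sessions — slightly above
nominal because quiet epochs (mean 7.8 s) and whisking epochs (mean
1.7 s) give rate samples with equal location but unequal variance,
which the rank test does not model.  Spike-timing changes: two-sample
KS on ISI pools.  Locomotion: paired *t*-test across cells on
whisking-only vs whisking+locomotion rates, plus the mean whisker-angle
shift.  No multiple-testing correction is applied across cells; the
per-cell α = 0.05 convention is reported as-is.  The CS-vs-SS change
correlation is Pearson (noted in output metadata, since the choice is
not forced by anything upstream).

## Latency estimation

Rate and position are cut into 3 s segments (1 s before to 2 s after
each bout onset or offset), z-scored per segment, cross-correlated over
lags ±500 ms and averaged.  Three numerical choices matter and were
each adopted after the naive variant measurably failed on ground truth:

1. **Common 6 Hz low-pass.**  Both series are restricted to the
   sub-6 Hz band (zero-phase) before correlating.  The latency of
   interest is between slow rate changes and the set-point transition;
   without the filter the 6–30 Hz rhythm imprints a carrier ripple on
   the correlogram whose sidelobes capture the nearest-extremum rule
   (errors of 30–70 ms on ±50 ms imposed lags).
2. **Per-lag overlap normalization.**  The observed curve is a linear
   (zero-padded) cross-correlation normalized per lag over the actual
   overlap, which keeps |c| ≤ 1 (Cauchy–Schwarz) without the
   constant-n taper; circular or biased-linear normalization tapers the
   correlogram toward lag 0 and drags the broad extremum several ms
   toward zero.
3. **Prominence-gated extrema.**  Candidate extrema need ≥ 5% of the
   curve's range in prominence, rejecting plateau micro-extrema that
   noise creates on the flat correlogram top.

The 95% band comes from 1000 surrogate curve sets with the rate
circularly shifted by uniform random offsets within each segment
(autocorrelation preserved, alignment destroyed).  The latency is the
lag of the extremum nearest zero that clears the band; ties break
toward the lead (negative lag); negative latency ⇔ rate leads position.
With these choices, imposed lags of −50/0/+50 ms are recovered to
≤ 2 ms on noiseless sessions and with ~±10 ms seed scatter (unbiased
median) on Poisson-spiking sessions.

The population latency distribution restricted to [−100, 100] ms is
tested with Hartigan's dip (own implementation, validated against an
exact linear-programming minimax-unimodal-fit oracle) and a bootstrap p
against a uniform null.  The dip is computed on the *raw* sample; the
5/10 ms bin size applies to the presentation histogram only, because
discretizing first concentrates unimodal samples into ties and pushes a
σ = 20 ms Gaussian to "non-unimodal" in half of all draws.

## Position encoding

The tuning curve is the occupancy-normalized rate in 1° position bins
over whisking epochs (bins with < 100 ms occupancy masked): spike
counts at the instantaneous position divided by time spent there.
Sampling the 100 ms-smoothed rate per position bin instead attenuates
the recovered slope by roughly var(set point)/var(position) — the
boxcar averages the rhythm out of the rate but not out of the regressor
— which under realistic whisking (±10° carrier) is a ~40%
underestimate; the spike-count estimator is unbiased.  An optional lag
aligns position to the rate it drives (a cell leading by 18 ms is tuned
to the position 18 ms after each spike); the pipeline uses the
cell's measured cross-correlation latency.

Fits use the rectified-linear tuning model max(0, a + g·x) (weighted
least squares seeded from both the plain WLS line and the steepest
adjacent-bin slope; a single start stalls when most bins are clipped at
zero).  The final gain is a plain occupancy-weighted linear regression
over the unclipped bins when at least five remain, otherwise the
rectified-model fit itself (a 30 Hz/deg retraction cell is linear over
only ~2°, i.e. two 1° bins).  Significance requires ANOVA p < 0.05 and
R² > 0.86.  Unidirectional fits are restricted to the modulated side of
the resting point (the mean quiet-epoch angle).

The directionality ratio divides the smaller of the two fitted extreme
rate changes (relative to the spontaneous quiet rate, rectified-model
prediction at the far end of each side) by the larger; a side whose fit
is non-significant or changes < 5 Hz contributes zero, so one-sided
cells get ratio 0 exactly.  Classification as bidirectional requires
ratio ≥ 0.2 (conservative relative to the 0.4–0.9 range typical of
clearly bidirectional cells) with both sides significant.  Note a
structural asymmetry of the rate model: decreases are bounded by the
~62 Hz baseline while increases are not, so bidirectional cells with
gain ≳ 18 Hz/deg have true ratio < 0.2 and legitimately classify as
unidirectional.

The linear encoding range is rate span / |gain| clipped to the observed
position span (for a clipped-linear cell these are identical by
construction), and the occupancy fraction is the whisking time spent
inside that range.  Over 20 generator cells with gains uniform in
[5, 35] Hz/deg the median relative gain error is ~3%.

## Phase tuning

Spike counts per 20 phase bins over (−π, π], normalized by the time
spent in each bin; modulation depth = (max − min)/mean.  With ~10⁴
spikes a raised-cosine tuned cell yields depth ≈ 1.95–2.05 (binning
shaves ~0.5% off the exact 2.0) and an untuned cell ~0.1–0.16 (the
expected extreme-value range of 20 Poisson bin rates — the depth of an
untuned cell is a decreasing function of spike count, not a fixed
small number).  The preferred phase is reported both as the circular
mean of spike phases (stable) and the argmax bin (flat-topped tuning
makes this jitter ±1 bin).

The tuning test compares spike-time phases with the all-time phase
sample of the same rhythmic intervals by a Kuiper statistic (rotation
invariant, so the phase origin is immaterial).  Conditional on the
trajectory, spikes of an untuned (Poisson) cell have phases that are
iid draws from the trajectory's own phase distribution; the full 1 ms
grid sample *is* that distribution, so it enters the test as a
reference population and the effective size is the spike count alone
(treating the grid as an independent iid sample makes the test
conservative — measured type-I 1% — while subsampling it at 10 ms
under-represents the null and inflates type-I to ~8%).  Spike phases
are interpolated on the unit circle between grid samples to avoid exact
ties with the reference.  Measured type-I: 5.9% over 1500 null
sessions; power at raised-cosine tuning with ≥ 1000 spikes: ~100%.
The Kuiper p uses the standard asymptotic series (own implementation;
calibrated on iid samples to 5.0% at α = 0.05).

## Decoding

The transfer function is a ridge-regularized FIR filter (lags ±500 ms
at 1 ms, covering observed SS-position latencies with margin) from
mean-centered rate to mean-centered position, estimated from the
Wiener–Hopf normal equations with a Toeplitz autocorrelation matrix and
FFT correlations; the ridge weight is chosen by generalized
cross-validation on the training split only (eigendecomposition of the
1001×1001 Toeplitz matrix makes the λ sweep cheap).  A frequency-domain
estimator was rejected to avoid windowing choices.  The default split
is 50/50 contiguous; recordings shorter than 300 s are refused.  The
filter is fit on raw position and scored against the set point, both
correlations emitted.

The kernel is identifiable only over the excitation bandwidth of the
rate; the identity- and known-kernel recovery checks therefore use
broadband test rates (with a band-limited rate the kernel's null-space
component is unconstrained and GCV cannot see it).  For scoring, the
held-out reconstruction is low-passed at 6 Hz before correlating with
the set point, comparing like with like: the FIR filter passes
supra-band spiking noise that would otherwise depress the score of a
faithful slow reconstruction (raw-reconstruction correlations sit
around 0.5–0.6; band-matched around 0.85–0.9 on generator sessions).
Held-out scoring never touches training samples (asserted).

## The synthetic generator

`SimConfig` defaults are the study conditions the pipeline targets:
250 frames/s video; bouts of mean 1.68 s alternating with quiet periods
of mean 7.82 s (shifted exponentials with a 0.5 s floor); a per-bout
carrier drawn from 8–16 Hz with ±10° amplitude and 100 ms raised-cosine
ramps; a 2 Hz-low-passed Ornstein–Uhlenbeck set-point drift (σ = 2°)
plus a +4° protraction of the set point during bouts (without it a
position-coding cell would show no whisk-vs-quiet rate change at all);
occasional quiet-period twitches (4° peak-to-peak single back-and-forth,
below the 5° exclusion floor); 0.3° measurement noise (magnitude is a
free parameter — it is not constrained by anything the pipeline
measures); SS baseline 61.9 Hz with gain 12.5 Hz/deg
(unidirectional-protraction default) and an 18 ms lead; CS at 1.6 Hz
with a 10 ms SS pause; 3.5% of bouts under locomotion (+5.5°
protraction).  Spike generation is exact Lewis–Shedler thinning.  The
multiplicative phase factor is normalized by its rhythmic-time mean so
it cannot confound gain recovery, and is applied only where the
envelope is rhythmic (phase is meaningless in quiet).

Equal seeds give bit-identical sessions (a single `SeedSequence` is
spawned into behavior and spiking streams).

What the generator does *not* emulate — and hence what passing tests do
not establish about real recordings: tracker artifacts and dropped
frames, non-Poisson SS regularity (real CV ≈ 0.9 arises partly from
refractoriness), slow nonstationarity of the baseline rate, whisker
interactions with objects, and any nonlinearity of the rate-position
relationship beyond one-sided rectification.  The benchmark shows the
estimators recover the model's parameters when the model holds, and
that the tests are calibrated under the model's null.

## Problem sizes

Calibration runs use 400–500 simulated cells (null) and 50–60
(power); recovery runs use 10 seeds per condition, 20 cells for gain
recovery, 15–20 seeds per decoding noise level; sessions are 120–600 s
depending on the eligibility the stage needs (≥ 60 s whisking for
tuning curves, > 300 s for decoding, > 20 s rhythmic for phase).  These
sizes put Monte-Carlo error comfortably inside each check's tolerance.
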