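# whiskcode

Analysis pipeline for asking how cerebellar Purkinje-cell simple-spike
(SS) firing encodes whisker kinematics in head-fixed mice, with a
synthetic-session generator that makes every stage testable against
known ground truth.

It is written for electrophysiologists who have, per recording, a
tracked whisker azimuth-angle series (degrees, uniformly sampled video)
and sorted SS / complex-spike (CS) event times, and who want the
standard whisking analyses end to end:

- **Kinematics** — zero-phase 30 Hz low-pass (4-pole Butterworth, run
  forward and reverse), up-sampling to 1 kHz, set point (< 6 Hz
  component), whisking phase and amplitude (Hilbert transform of the
  6–30 Hz band; phase 0 = maximal protraction, ±π = maximal
  retraction), and epoch segmentation into quiet / whisking / excluded
  (bouts < 500 ms and single back-and-forth twitches < 5° peak-to-peak
  are excluded from both pools; treadmill activity ≥ 400 ms is labeled
  locomotion).
- **Spike statistics** — instantaneous rate (100 ms boxcar, 1 ms
  steps), per-epoch rates, ISI coefficient of variation, and the
  peri-CS SS histogram used to validate sorting (~10 ms post-CS pause).
- **Modulation** — per-epoch Mann–Whitney rate test (p < 0.05),
  two-sample KS test on ISI distributions, paired *t*-test for the
  locomotion effect.
- **Latency** — segment-averaged normalized cross-correlation between
  SS rate and whisker position around bout onsets/offsets (3 s
  segments, lags ±500 ms, circular-shift surrogate 95% band; negative
  latency = spikes lead movement), and Hartigan's dip test for
  multimodality of the population latency distribution.
- **Encoding** — occupancy-normalized position tuning curves (1° bins),
  rectified-linear fits with gain *g* (Hz/deg), the directionality
  ratio min(|Δr₊|, |Δr₋|)/max(|Δr₊|, |Δr₋|) classifying cells as
  unidirectional (ratio 0) or bidirectional, and linear encoding-range
  statistics (range ≈ rate span / |g|).
- **Phase tuning** — 20-bin occupancy-normalized phase histograms,
  modulation depth (max − min)/mean, and a Kuiper test of spike-phase
  against all-time phase.
- **Decoding** — a ridge-regularized FIR transfer function (lags
  ±500 ms) from SS rate to whisker position, fit on a training split
  and scored by the Pearson correlation between the held-out
  reconstruction and the whisker set point.

The model at the core: SS rate is a rectified linear function of
(time-lagged) whisker position around a spontaneous rate r₀,

    r(t) = max(0, r0 + g · (θ(t − τ) − θ_rest)),

optionally multiplied by a raised-cosine phase factor
(1 + d·cos(φ − φ₀)); τ < 0 means the cell leads the whisker.  The
synthetic generator (`whiskcode.synthetic`) simulates whisking behavior
(1.68 s mean bouts, 7.82 s mean quiet periods, 6–30 Hz rhythm on a
drifting set point) and draws SS trains from this model by
Lewis–Shedler thinning, plus ~1.6 Hz CS events that each silence SSs
for 10 ms.

## Worked example

```python
import whiskcode as wc

cfg = wc.SimConfig(duration=380.0, seed=11, gain=14.0,
                   direction_mode="bidirectional")
session = wc.simulate_session(cfg)
epochs  = wc.segment_epochs(session.kin)
rate    = wc.instantaneous_rate(session.spikes)

mod = wc.modulation_report(session.spikes, epochs)
lat = wc.xcorr_latency(rate, session.kin,
                       [s for s, _ in epochs.intervals("whisking")])
curve = wc.tuning_curve(session.spikes, session.kin, epochs,
                        lag_s=lat.latency_s)
fit = wc.fit_linear_encoding(curve)
dec = wc.decode_session(rate, session.kin)

print(f"whisking {epochs.total('whisking'):.0f} s in "
      f"{len(epochs.intervals('whisking'))} bouts; "
      f"quiet rate {mod.rate_quiet:.1f} Hz, whisking rate "
      f"{mod.rate_whisk:.1f} Hz ({mod.rel_change:+.0f}%, "
      f"Mann-Whitney p = {mod.p_rate:.1e})")
print(f"latency {lat.latency_s*1000:+.0f} ms (peak correlation "
      f"{lat.peak_corr:.2f}, {lat.n_segments} segments)")
print(f"{fit.direction_class} cell: gain {fit.gain:.1f} Hz/deg, "
      f"R^2 = {fit.r2:.3f} (true gain 14.0)")
print(f"held-out set-point reconstruction r = {dec.r_setpoint:.2f}")
```

prints

```
whisking 73 s in 41 bouts; quiet rate 61.4 Hz, whisking rate 116.0 Hz (+89%, Mann-Whitney p = 1.0e-16)
latency -23 ms (peak correlation 0.71, 41 segments)
bidirectional cell: gain 12.5 Hz/deg, R^2 = 0.994 (true gain 14.0)
held-out set-point reconstruction r = 0.89
```

Reading: this simulated cell fires at ~61 Hz at rest and nearly doubles
its rate during whisking; its rate change leads the whisker by ~23 ms
(efferent-like timing); its rate is linear in whisker position with a
recovered gain close to the generator's 14 Hz/deg; and a linear filter
fit on half the recording reconstructs the whisker set point on the
held-out half with r ≈ 0.9.

A thin CLI mirrors the library (`whiskcode simulate | kinematics |
rates | modulation | latency | encoding | phase | decode`); every
command reads and writes plain CSV/JSON/YAML.

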