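"""Filtering, set point, phase convention and epoch segmentation."""

import numpy as np
import pytest

import whiskcode as wc
from whiskcode.kinematics import (
    EpochSet,
    SegmentationParams,
    WhiskerTrace,
    compute_phase,
    compute_setpoint,
    preprocess_trace,
    rhythmic_epochs,
    segment_epochs,
    zero_phase_filter,
)


def butter2pass_gain(f, fc=30.0, order=4):
    """Closed-form two-pass amplitude gain |H(f)|^2 of an analog Butterworth."""
    return 1.0 / (1.0 + (f / fc) ** (2 * order))


def sine_trace(freq, fs, duration=10.0, amp=1.0, offset=0.0):
    t = np.arange(int(duration * fs)) / fs
    return WhiskerTrace(fs=fs, angle=offset + amp * np.sin(2 * np.pi * freq * t))


class TestFiltering:
    @pytest.mark.parametrize("freq", [5.0, 30.0, 50.0])
    def test_two_pass_gain_matches_analog_formula(self, freq):
        # fs high enough that bilinear warping is negligible at 50 Hz
        fs = 5000.0
        tr = sine_trace(freq, fs, duration=20.0)
        y = zero_phase_filter(tr.angle, fs, 30.0, "lowpass")
        mid = slice(int(5 * fs), int(15 * fs))
        gain = np.ptp(y[mid]) / np.ptp(tr.angle[mid])
        expected = butter2pass_gain(freq)
        assert gain == pytest.approx(expected, rel=0.01)

    def test_dc_invariance(self):
        tr = WhiskerTrace(fs=250.0, angle=np.full(2500, 12.0))
        kin = preprocess_trace(tr)
        assert kin.fs == 1000.0
        assert np.allclose(kin.angle_f, 12.0, atol=1e-6)

    def test_inband_sinusoid_amplitude_and_zero_phase(self):
        tr = sine_trace(5.0, 250.0, duration=10.0)
        kin = preprocess_trace(tr)
        t = np.arange(kin.n) / kin.fs
        ref = np.sin(2 * np.pi * 5.0 * t)
        mid = slice(2000, 8000)
        amp = np.ptp(kin.angle_f[mid]) / 2
        assert amp == pytest.approx(1.0, rel=0.01)
        # zero net phase: cross-correlation with the analytic input peaks at lag 0
        c = np.correlate(kin.angle_f[mid] - kin.angle_f[mid].mean(),
                         ref[mid] - ref[mid].mean(), mode="full")
        assert abs(np.argmax(c) - (len(c) // 2)) == 0

    def test_duration_preserved_within_one_sample(self):
        tr = sine_trace(3.0, 250.0, duration=7.3)
        kin = preprocess_trace(tr)
        assert abs(kin.duration - tr.duration) <= 1.0 / kin.fs + 1e-9

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError, match="30 Hz"):
            preprocess_trace(WhiskerTrace(fs=50.0, angle=np.zeros(200)))

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="short"):
            preprocess_trace(WhiskerTrace(fs=250.0, angle=np.zeros(100)))


class TestSetpoint:
    def test_constant_passthrough(self):
        kin = preprocess_trace(WhiskerTrace(fs=250.0, angle=np.full(2500, 7.0)))
        kin = compute_setpoint(kin)
        assert np.allclose(kin.setpoint, 7.0, atol=1e-6)

    def test_fast_oscillation_removed(self):
        # 10 Hz is attenuated ~25x by the two-pass 6 Hz filter
        tr = sine_trace(10.0, 250.0, duration=10.0, amp=10.0, offset=20.0)
        kin = compute_setpoint(preprocess_trace(tr))
        mid = slice(1000, 9000)
        assert np.all(np.abs(kin.setpoint[mid] - 20.0) < 0.5)

    def test_slow_ramp_tracked(self):
        t = np.arange(2500) / 250.0
        tr = WhiskerTrace(fs=250.0, angle=t)  # 0 -> 10 deg over 10 s
        kin = compute_setpoint(preprocess_trace(tr))
        tt = np.arange(kin.n) / kin.fs
        mid = slice(1000, 9000)
        assert np.all(np.abs(kin.setpoint[mid] - tt[mid]) < 0.2)

    def test_linear_operators_commute(self):
        tr = sine_trace(4.0, 250.0, duration=8.0, amp=5.0, offset=15.0)
        a = compute_setpoint(preprocess_trace(tr)).setpoint
        # set-point filter applied at the native rate, then preprocessing
        pre = WhiskerTrace(fs=250.0,
                           angle=zero_phase_filter(tr.angle, 250.0, 6.0))
        b = preprocess_trace(pre).angle_f
        mid = slice(500, 7500)
        assert np.allclose(a[mid], b[mid], atol=0.02)


class TestPhase:
    def test_zero_at_protraction_peaks_pi_at_troughs(self):
        tr = sine_trace(10.0, 250.0, duration=10.0, amp=10.0, offset=20.0)
        kin = compute_phase(compute_setpoint(preprocess_trace(tr)))
        x = kin.angle_f - kin.setpoint
        mid = np.arange(1000, kin.n - 1000)
        peaks = mid[(x[mid] > x[mid - 1]) & (x[mid] >= x[mid + 1])]
        troughs = mid[(x[mid] < x[mid - 1]) & (x[mid] <= x[mid + 1])]
        assert np.all(np.abs(kin.phase[peaks]) < 0.05)
        assert np.all(np.pi - np.abs(kin.phase[troughs]) < 0.05)

    def test_chirp_instantaneous_frequency_vs_zero_crossing_oracle(self):
        fs, dur = 250.0, 20.0
        t = np.arange(int(fs * dur)) / fs
        f0, f1 = 8.0, 15.0
        phase_true = 2 * np.pi * (f0 * t + (f1 - f0) * t**2 / (2 * dur))
        tr = WhiskerTrace(fs=fs, angle=10 * np.sin(phase_true) + 20)
        kin = compute_phase(compute_setpoint(preprocess_trace(tr)))
        mid = slice(2000, kin.n - 2000)
        unwrapped = np.unwrap(kin.phase)
        assert np.all(np.diff(unwrapped[mid]) > -1e-9)
        inst_f = np.diff(unwrapped[mid]) * kin.fs / (2 * np.pi)
        # oracle: frequency from intervals between zero crossings of the band signal
        x = kin.angle_f - kin.setpoint
        zc = np.flatnonzero((x[:-1] < 0) & (x[1:] >= 0))
        zc = zc[(zc > 2000) & (zc < kin.n - 2000)]
        f_oracle = kin.fs / np.diff(zc)
        f_est = np.array([inst_f[(a - 2000):(b - 2000)].mean()
                          for a, b in zip(zc[:-1], zc[1:])])
        assert np.all(np.abs(f_est - f_oracle) / f_oracle < 0.05)


def one_bout_trace(fs=250.0, quiet=10.0, bout=1.0, amp=10.0, freq=10.0, seed=0):
    rng = np.random.default_rng(seed)
    n = int(fs * quiet)
    t = np.arange(n) / fs
    x = np.full(n, 15.0)
    s0 = quiet / 2
    s1 = s0 + bout
    seg = (t >= s0) & (t < s1)
    ramp = 0.1
    env = np.clip(np.minimum(t[seg] - s0, s1 - t[seg]) / ramp, 0.0, 1.0)
    env = 0.5 * (1 - np.cos(np.pi * env))
    x[seg] += amp * env * np.sin(2 * np.pi * freq * (t[seg] - s0))
    x += rng.normal(0, 0.2, n)
    return WhiskerTrace(fs=fs, angle=x), s0, s1


class TestSegmentation:
    def test_flat_trace_single_quiet_epoch(self):
        kin = wc.analyze_trace(WhiskerTrace(fs=250.0, angle=np.full(2500, 15.0)))
        ep = segment_epochs(kin)
        assert ep.intervals("whisking") == []
        assert ep.total("quiet") == pytest.approx(10.0, abs=1e-6)

    def test_single_bout_detected_with_accurate_onset(self):
        tr, s0, s1 = one_bout_trace()
        ep = segment_epochs(wc.analyze_trace(tr))
        ivs = ep.intervals("whisking")
        assert len(ivs) == 1
        assert abs(ivs[0][0] - s0) < 0.04
        assert abs(ivs[0][1] - s1) < 0.04

    def test_small_twitch_excluded_not_whisking(self):
        fs = 250.0
        t = np.arange(int(fs * 10)) / fs
        x = np.full(t.size, 15.0)
        seg = (t >= 5.0) & (t < 5.12)  # single back-and-forth, 4 deg p2p
        x[seg] += 2.0 * np.sin(2 * np.pi * (t[seg] - 5.0) / 0.12)
        ep = segment_epochs(wc.analyze_trace(WhiskerTrace(fs=fs, angle=x)))
        assert ep.intervals("whisking") == []
        assert ep.total("excluded") > 0

    def test_sub_500ms_bout_excluded(self):
        tr, _, _ = one_bout_trace(bout=0.3)
        ep = segment_epochs(wc.analyze_trace(tr))
        assert ep.intervals("whisking") == []
        assert ep.total("excluded") > 0

    def test_epochs_tile_recording(self, default_session):
        ep = segment_epochs(default_session.kin)
        prim = sorted(
            iv for lab in ("quiet", "whisking", "excluded")
            for iv in [(s, e) for s, e in ep.intervals(lab)]
        )
        t = 0.0
        for s, e in prim:
            assert s == pytest.approx(t, abs=1e-6)
            t = e
        assert t == pytest.approx(default_session.kin.duration, abs=1e-6)

    def test_locomotion_overlay(self):
        tr, s0, s1 = one_bout_trace(bout=1.5)
        tm = np.zeros(tr.angle.size)
        tm[(tr.times >= s0) & (tr.times < s0 + 1.0)] = 1.0
        ep = segment_epochs(wc.analyze_trace(tr), treadmill=tm, treadmill_fs=tr.fs)
        assert len(ep.intervals("locomotion")) == 1
        # short treadmill blips (< 400 ms) are ignored
        tm2 = np.zeros(tr.angle.size)
        tm2[:50] = 1.0  # 200 ms at 250 Hz
        ep2 = segment_epochs(wc.analyze_trace(tr), treadmill=tm2, treadmill_fs=tr.fs)
        assert ep2.intervals("locomotion") == []


class TestRestingPoint:
    def test_flat_trace(self):
        kin = wc.analyze_trace(WhiskerTrace(fs=250.0, angle=np.full(2500, 15.0)))
        ep = segment_epochs(kin)
        assert wc.resting_point(kin, ep) == pytest.approx(15.0, abs=0.01)

    def test_simulated_resting_angle_recovered(self):
        s = wc.simulate_session(wc.SimConfig(duration=60.0, seed=5,
                                             resting_angle=20.0))
        ep = segment_epochs(s.kin)
        assert wc.resting_point(s.kin, ep) == pytest.approx(20.0, abs=0.5)

    def test_no_quiet_time_refused(self):
        kin = wc.analyze_trace(WhiskerTrace(fs=250.0, angle=np.full(2500, 15.0)))
        ep = EpochSet([(0.0, 10.0, "whisking")], duration=10.0, complete=False)
        with pytest.raises(ValueError, match="quiet"):
            wc.resting_point(kin, ep)


class TestRhythmicEpochs:
    def test_sustained_whisking_eligible(self, rhythmic_session):
        s, ep, rhy, elig = rhythmic_session
        assert elig
        assert rhy.total("rhythmic") > 20.0

    def test_short_rhythmic_time_ineligible(self):
        tr, _, _ = one_bout_trace(quiet=20.0, bout=5.0)
        kin = wc.analyze_trace(tr)
        ep = segment_epochs(kin)
        rhy, elig = rhythmic_epochs(kin, ep)
        assert not elig

    def test_broadband_noise_bout_mostly_non_rhythmic(self):
        rng = np.random.default_rng(3)
        fs = 250.0
        x = np.full(int(fs * 30), 15.0)
        t = np.arange(x.size) / fs
        bout = (t >= 5) & (t < 25)
        x[bout] += rng.normal(0, 3.0, bout.sum())  # broadband, weak 6-30 Hz power
        kin = wc.analyze_trace(WhiskerTrace(fs=fs, angle=x))
        ep = segment_epochs(kin)
        rhy, _ = rhythmic_epochs(kin, ep)
        assert rhy.total("rhythmic") < 0.2 * 20.0
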