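"""Synthetic whisking sessions with linearly-encoded Purkinje-cell spikes.

The generator emulates the behavior of a head-fixed mouse alternating
between quiet periods and self-initiated whisking bouts (mean bout
duration 1.68 s, mean quiet period 7.82 s, both with a 0.5 s floor), and
a Purkinje cell whose simple-spike (SS) rate is a rectified linear
function of (time-lagged) whisker position around a baseline of 61.9 Hz,
with rare complex spikes (CS, 1.6 Hz) each followed by a ~10 ms SS pause.

Whisker angle model (degrees, protraction positive)::

    angle(t) = resting + env(t) * [shift + drift(t)] + env(t) * carrier(t)
               + twitches(t) + noise(t)

where ``env`` ramps between 0 and 1 at bout edges, ``drift`` is an
Ornstein-Uhlenbeck set-point walk low-passed at 2 Hz, ``carrier`` is a
per-bout constant-frequency rhythm drawn from 6-30 Hz, ``shift`` is the
protraction of the set point that accompanies whisking, and twitches are
single back-and-forth deflections below 5 degrees peak-to-peak occurring
in quiet periods.

SS rate model (Hz), evaluated on the 1 kHz kinematics::

    r(t) = max(0, baseline + m(angle_f(t - latency) - resting))
           * (1 + d cos(phase(t - latency) - phase_pref)) / Z

``m`` is the signed gain, one-sided for unidirectional cells; negative
``latency`` makes the rate *lead* the movement.  The multiplicative phase
factor (depth ``d``, applied only within rhythmic whisking and normalized
by its rhythmic-time mean ``Z``) preserves the mean rate so that gain
recovery is unconfounded.  Spikes are drawn by Lewis-Shedler thinning of
an inhomogeneous Poisson process; CS times are homogeneous Poisson and
every CS deletes SS events in the following ``cs_pause`` window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .kinematics import (
    FS_ANALYSIS,
    Kinematics,
    SegmentationParams,
    WhiskerTrace,
    analyze_trace,
)
from .spikes import SpikeTrain

DIRECTION_MODES = (
    "unidirectional-protraction",
    "unidirectional-retraction",
    "bidirectional",
)


@dataclass
class SimConfig:
    """Ground-truth parameters of a simulated cell/session.

    Defaults reproduce the study conditions of the source recordings:
    250 frames/s video, 1.68 s mean bouts vs 7.82 s mean quiet periods,
    61.9 Hz SS baseline, 1.6 Hz CS rate with a 10 ms pause, and a
    unidirectional protraction cell of gain 12.5 Hz/deg whose rate change
    leads the whisker by ~18 ms.
    """

    duration: float = 300.0          # s
    fs_video: float = 250.0          # Hz
    seed: int = 0
    # --- behavior ---
    resting_angle: float = 15.0      # deg
    bout_rate: float | None = None   # bouts/s; 0 disables bouts, None -> quiet_dur_mean
    bout_dur_mean: float = 1.68      # s (0.5 s floor, shifted exponential)
    quiet_dur_mean: float = 7.82     # s (0.5 s floor)
    min_epoch: float = 0.5           # s; floor of bout/quiet durations
    setpoint_sigma: float = 2.0      # deg; slow set-point drift inside bouts
    bout_setpoint_shift: float = 4.0  # deg; protraction of set point while whisking
    carrier_freq_range: tuple = (8.0, 16.0)  # Hz, within [6, 30]
    carrier_amp: float = 10.0        # deg (half peak-to-peak of the rhythm)
    ramp: float = 0.1                # s; envelope ramp at bout edges
    twitch_rate: float = 0.05        # events/s during quiet
    twitch_p2p: float = 4.0          # deg peak-to-peak (< 5 -> excluded by rule)
    angle_noise_sd: float = 0.3      # deg; measurement noise on the video trace
    # --- encoder ---
    baseline_rate_ss: float = 61.9   # Hz
    gain: float = 12.5               # Hz/deg, signed
    latency: float = -0.018          # s; negative = spikes lead movement
    direction_mode: str = "unidirectional-protraction"
    phase_mod_depth: float = 0.0     # >= 0
    phase_pref: float = 0.0          # rad
    rate_noise_sd: float = 0.0       # Hz; additive encoder noise before thinning
    cs_rate: float = 1.6             # Hz
    cs_pause: float = 0.010          # s
    # --- locomotion ---
    locomotion_fraction: float = 0.035  # fraction of bouts spent running
    locomotion_angle_shift: float = 5.5  # deg extra protraction while running
    locomotion_rate_boost: float = 0.0   # Hz added to the SS rate while running

    def __post_init__(self) -> None:
        if not np.isfinite(self.duration) or self.duration <= 0:
            raise ValueError("duration must be positive and finite")
        for name in ("bout_dur_mean", "quiet_dur_mean", "twitch_rate",
                     "baseline_rate_ss", "cs_rate", "cs_pause",
                     "phase_mod_depth", "angle_noise_sd", "rate_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.carrier_freq_range
        if not (6.0 <= lo <= hi <= 30.0):
            raise ValueError("carrier_freq_range must lie within [6, 30] Hz")
        if abs(self.latency) >= 0.5:
            raise ValueError("latency magnitude must be < 0.5 s")
        if self.direction_mode not in DIRECTION_MODES:
            raise ValueError(f"direction_mode must be one of {DIRECTION_MODES}")
        if not 0.0 <= self.locomotion_fraction <= 1.0:
            raise ValueError("locomotion_fraction must lie in [0, 1]")


@dataclass
class SimSession:
    """A complete simulated recording with its ground truth."""

    trace: WhiskerTrace
    treadmill: np.ndarray           # binary, at trace.fs
    kin: Kinematics                 # full pipeline output at 1 kHz
    spikes: SpikeTrain
    truth: dict


def _shifted_exp(rng: np.random.Generator, mean: float, floor: float) -> float:
    if mean <= floor:
        return max(mean, floor)
    return floor + rng.exponential(mean - floor)


def _draw_bouts(cfg: SimConfig, rng: np.random.Generator):
    """Alternating quiet/bout intervals; returns list of (start, end)."""
    if cfg.bout_rate == 0 or cfg.bout_dur_mean == 0:
        return []
    quiet_mean = cfg.quiet_dur_mean
    if cfg.bout_rate is not None and cfg.bout_rate > 0:
        quiet_mean = max(1.0 / cfg.bout_rate - cfg.bout_dur_mean, cfg.min_epoch)
    bouts = []
    t = _shifted_exp(rng, quiet_mean, cfg.min_epoch)
    while t < cfg.duration - cfg.min_epoch:
        d = _shifted_exp(rng, cfg.bout_dur_mean, cfg.min_epoch)
        end = min(t + d, cfg.duration)
        bouts.append((t, end))
        t = end + _shifted_exp(rng, quiet_mean, cfg.min_epoch)
    return bouts


def _envelope(n: int, fs: float, bouts, ramp: float) -> np.ndarray:
    """0-1 envelope with raised-cosine ramps at bout edges."""
    env = np.zeros(n)
    t = np.arange(n) / fs
    for s, e in bouts:
        r = min(ramp, (e - s) / 2.0)
        seg = (t >= s) & (t < e)
        u = np.zeros(n)
        u[seg] = 1.0
        rise = (t >= s) & (t < s + r)
        u[rise] = 0.5 * (1 - np.cos(np.pi * (t[rise] - s) / r))
        fall = (t >= e - r) & (t < e)
        u[fall] = 0.5 * (1 - np.cos(np.pi * (e - t[fall]) / r))
        env = np.maximum(env, u)
    return env


def _ou_lowpassed(n: int, fs: float, sigma: float, rng: np.random.Generator):
    """Unit-free OU walk (tau = 1 s), low-passed below 2 Hz, scaled to sigma."""
    if sigma == 0 or n == 0:
        return np.zeros(n)
    tau = 1.0
    dt = 1.0 / fs
    x = np.empty(n)
    x[0] = rng.standard_normal()
    a = 1.0 - dt / tau
    b = np.sqrt(2.0 * dt / tau)
    eta = rng.standard_normal(n - 1)
    for i in range(1, n):
        x[i] = a * x[i - 1] + b * eta[i - 1]
    from .kinematics import zero_phase_filter

    x = zero_phase_filter(x, fs, 2.0, "lowpass")
    sd = np.std(x)
    return x * (sigma / sd) if sd > 0 else x


def simulate_whisking(config: SimConfig, rng: np.random.Generator | None = None):
    """Generate the whisker-angle trace, treadmill signal and ground truth.

    Returns ``(trace, treadmill, truth)`` where ``truth`` records the
    realized bout/locomotion intervals, per-bout carrier frequencies and
    every encoder parameter.  Identical seeds give identical output.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[0])
    fs = config.fs_video
    n = int(round(config.duration * fs))
    t = np.arange(n) / fs

    bouts = _draw_bouts(config, rng)
    env = _envelope(n, fs, bouts, config.ramp)
    drift = _ou_lowpassed(n, fs, config.setpoint_sigma, rng)

    carrier = np.zeros(n)
    freqs = []
    for s, e in bouts:
        f = rng.uniform(*config.carrier_freq_range)
        phi0 = rng.uniform(0, 2 * np.pi)
        seg = (t >= s) & (t < e)
        carrier[seg] = np.cos(2 * np.pi * f * (t[seg] - s) + phi0)
        freqs.append(f)

    angle = (
        config.resting_angle
        + env * (config.bout_setpoint_shift + drift)
        + env * config.carrier_amp * carrier
    )

    # quiet-period twitches: one back-and-forth sine period, < 5 deg p2p
    twitch_times = []
    if config.twitch_rate > 0:
        quiet_gaps = []
        prev = 0.0
        for s, e in bouts + [(config.duration, config.duration)]:
            if s - prev > 0.6:
                quiet_gaps.append((prev + 0.2, s - 0.4))
            prev = e
        for g0, g1 in quiet_gaps:
            k = rng.poisson(config.twitch_rate * (g1 - g0))
            twitch_times.extend(np.sort(rng.uniform(g0, g1, size=k)))
        dur = 0.12
        for t0 in twitch_times:
            seg = (t >= t0) & (t < t0 + dur)
            angle[seg] += (config.twitch_p2p / 2.0) * np.sin(
                2 * np.pi * (t[seg] - t0) / dur
            )

    if config.angle_noise_sd > 0:
        angle = angle + rng.normal(0.0, config.angle_noise_sd, size=n)

    # locomotion: a subset of bouts, treadmill active for the whole bout
    treadmill = np.zeros(n)
    loco = []
    for s, e in bouts:
        if rng.uniform() < config.locomotion_fraction:
            loco.append((s, e))
            treadmill[(t >= s) & (t < e)] = 1.0
            seg = (t >= s) & (t < e)
            angle[seg] += config.locomotion_angle_shift * env[seg]

    truth = {
        "config": asdict(config),
        "bouts": [(float(s), float(e)) for s, e in bouts],
        "bout_freqs": [float(f) for f in freqs],
        "locomotion": [(float(s), float(e)) for s, e in loco],
        "twitch_times": [float(x) for x in twitch_times],
    }
    return WhiskerTrace(fs=fs, angle=angle), treadmill, truth


def encoder_rate(
    kin: Kinematics,
    config: SimConfig,
    locomotion=None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Ground-truth SS rate (Hz) at 1 kHz implied by the kinematics.

    This is the deterministic part of the generative model; tests use it
    directly as a noiseless rate series.
    """
    if kin.fs != FS_ANALYSIS:
        raise ValueError("encoder requires kinematics sampled at 1 kHz")
    if kin.phase is None or kin.amplitude is None:
        raise ValueError("kinematics must carry phase and amplitude")
    n = kin.n
    shift = int(round(config.latency * kin.fs))
    # negative latency -> rate leads: r(t) = f(angle(t - latency))
    idx = np.clip(np.arange(n) - shift, 0, n - 1)
    x = kin.angle_f[idx] - config.resting_angle

    if config.direction_mode == "unidirectional-protraction":
        m = config.gain * np.maximum(x, 0.0)
    elif config.direction_mode == "unidirectional-retraction":
        m = config.gain * np.minimum(x, 0.0)
    else:
        m = config.gain * x
    r = np.maximum(config.baseline_rate_ss + m, 0.0)

    if config.phase_mod_depth > 0:
        rhythmic = kin.amplitude[idx] >= SegmentationParams().rhythm_threshold_deg
        if np.any(rhythmic):
            fac = 1.0 + config.phase_mod_depth * np.cos(
                kin.phase[idx] - config.phase_pref
            )
            z = float(np.mean(fac[rhythmic]))
            scale = np.ones(n)
            scale[rhythmic] = fac[rhythmic] / z
            r = r * scale

    if locomotion and config.locomotion_rate_boost:
        tvec = kin.times
        for s, e in locomotion:
            r[(tvec >= s) & (tvec < e)] += config.locomotion_rate_boost

    if config.rate_noise_sd > 0:
        if rng is None:
            raise ValueError("rate_noise_sd > 0 requires an rng")
        r = np.maximum(r + rng.normal(0.0, config.rate_noise_sd, size=n), 0.0)
    return r


def _thin_poisson(rate: np.ndarray, fs: float, rng: np.random.Generator):
    """Exact inhomogeneous-Poisson event times by Lewis-Shedler thinning."""
    lam_max = float(rate.max(initial=0.0))
    duration = rate.size / fs
    if lam_max <= 0:
        return np.empty(0)
    n_cand = rng.poisson(lam_max * duration)
    cand = np.sort(rng.uniform(0.0, duration, size=n_cand))
    local = rate[np.minimum((cand * fs).astype(int), rate.size - 1)]
    keep = rng.uniform(0.0, lam_max, size=n_cand) < local
    return cand[keep]


def simulate_spikes(
    kin: Kinematics,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    locomotion=None,
) -> SpikeTrain:
    """Draw SS and CS trains from the rectified-linear encoder by thinning."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    rate = encoder_rate(kin, config, locomotion=locomotion,
                        rng=rng if config.rate_noise_sd > 0 else None)
    ss = _thin_poisson(rate, kin.fs, rng)
    duration = kin.duration
    n_cs = rng.poisson(config.cs_rate * duration)
    cs = np.sort(rng.uniform(0.0, duration, size=n_cs))
    if cs.size and config.cs_pause > 0 and ss.size:
        dead = np.zeros(ss.size, dtype=bool)
        for c in cs:
            dead |= (ss > c) & (ss <= c + config.cs_pause)
        ss = ss[~dead]
    return SpikeTrain(ss_times=ss, cs_times=cs, t_start=0.0, t_end=duration)


def simulate_session(config: SimConfig) -> SimSession:
    """End-to-end simulated recording: behavior, kinematics, spike trains."""
    seq = np.random.SeedSequence(config.seed).spawn(2)
    trace, treadmill, truth = simulate_whisking(config, np.random.default_rng(seq[0]))
    kin = analyze_trace(trace)
    spikes = simulate_spikes(
        kin, config, np.random.default_rng(seq[1]), locomotion=truth["locomotion"]
    )
    return SimSession(trace=trace, treadmill=treadmill, kin=kin,
                      spikes=spikes, truth=truth)
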