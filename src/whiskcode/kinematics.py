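"""Whisker-angle kinematics: filtering, set point, phase, epoch segmentation.

The processing chain mirrors standard head-fixed whisking analyses:

1. the tracked azimuth angle (protraction = increasing angle) is low-pass
   filtered at 30 Hz with a 4-pole Butterworth run forward and reverse
   (zero phase), then up-sampled to 1 kHz by polyphase resampling;
2. the *set point* is the < 6 Hz component of the filtered angle;
3. the *phase* is the angle of the analytic (Hilbert) signal of the
   6-30 Hz band-passed angle, with phase 0 at maximal protraction and
   +/- pi at maximal retraction; the analytic-signal magnitude is the
   whisking amplitude envelope;
4. the recording is segmented into quiet / whisking / excluded epochs from
   the amplitude envelope, with the classic exclusion rules: whisking
   epochs shorter than 500 ms and single back-and-forth twitches smaller
   than 5 degrees peak-to-peak are removed from both pools, and treadmill
   activity lasting at least 400 ms marks locomotion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
from scipy import signal

FS_ANALYSIS = 1000.0  # Hz; everything downstream of preprocessing runs at 1 kHz

PRIMARY_LABELS = ("quiet", "whisking", "excluded")


@dataclass
class SegmentationParams:
    """Tunable thresholds of the envelope-based epoch detector.

    The whisking threshold of 2.5 deg on the 6-30 Hz amplitude envelope
    corresponds to the 5 deg peak-to-peak floor below which isolated
    deflections count as twitches rather than whisking.
    """

    whisk_threshold_deg: float = 2.5   # envelope level that defines whisking
    onset_floor_deg: float = 1.0       # bout edges extended down to this level
    merge_gap_s: float = 0.25          # gaps between active stretches merged below this
    min_bout_s: float = 0.5            # shorter candidate bouts are excluded
    min_twitch_p2p_deg: float = 5.0    # single back-and-forth below this -> excluded
    locomotion_min_s: float = 0.4      # treadmill activity must last this long
    rhythm_threshold_deg: float = 2.5  # sustained envelope for rhythmic whisking
    rhythm_min_s: float = 0.3          # ~3 cycles of a 10 Hz whisk
    rhythm_total_s: float = 20.0       # phase-tuning eligibility
    edge_trim_s: float = 0.2           # recording edges excluded from phase statistics


@dataclass
class WhiskerTrace:
    """Raw whisker azimuth-angle time series.

    Parameters
    ----------
    fs : float
        Sampling rate in Hz (250 Hz for the standard high-speed video).
    angle : ndarray
        Azimuth angle in degrees; increasing angle = protraction.
    """

    fs: float
    angle: np.ndarray

    def __post_init__(self) -> None:
        self.angle = np.asarray(self.angle, dtype=float)
        if self.fs <= 0 or not np.isfinite(self.fs):
            raise ValueError("sampling rate must be positive and finite")
        if self.angle.ndim != 1 or self.angle.size < 2:
            raise ValueError("angle must be a 1-d series with >= 2 samples")
        if not np.all(np.isfinite(self.angle)):
            raise ValueError("angle contains non-finite values")

    @property
    def duration(self) -> float:
        return self.angle.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.angle.size) / self.fs


@dataclass
class Kinematics:
    """Filtered kinematic series at 1 kHz.

    ``angle_f`` is always populated; ``setpoint``, ``phase`` and
    ``amplitude`` are filled in by :func:`compute_setpoint` and
    :func:`compute_phase`.
    """

    fs: float
    angle_f: np.ndarray
    setpoint: np.ndarray | None = None
    phase: np.ndarray | None = None
    amplitude: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.angle_f.size

    @property
    def duration(self) -> float:
        return self.n / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n) / self.fs


class EpochSet:
    """Labeled, disjoint time intervals (half-open ``[start, end)`` seconds).

    The primary labels quiet / whisking / excluded tile the recording;
    locomotion intervals are an overlay (they coincide with whisking) and
    are exempt from the tiling check, as are the rhythmic sub-intervals.
    """

    def __init__(self, intervals, duration: float, complete: bool = True):
        self._intervals = sorted(
            (float(s), float(e), str(lab)) for s, e, lab in intervals
        )
        self.duration = float(duration)
        self.complete = bool(complete)
        for s, e, _ in self._intervals:
            if not (0.0 <= s < e <= self.duration + 1e-9):
                raise ValueError(f"interval ({s}, {e}) outside [0, {self.duration}]")
        if complete:
            self._check_tiling()

    def _check_tiling(self) -> None:
        prim = [iv for iv in self._intervals if iv[2] in PRIMARY_LABELS]
        t = 0.0
        for s, e, lab in prim:
            if abs(s - t) > 1e-6:
                raise ValueError(f"primary epochs do not tile: gap/overlap at {s}")
            t = e
        if abs(t - self.duration) > 1e-6:
            raise ValueError("primary epochs do not cover the recording")

    def __iter__(self):
        return iter(self._intervals)

    def __len__(self) -> int:
        return len(self._intervals)

    def intervals(self, label: str | None = None):
        """List of (start, end) pairs, optionally restricted to one label."""
        if label is None:
            return [(s, e) for s, e, _ in self._intervals]
        return [(s, e) for s, e, lab in self._intervals if lab == label]

    def total(self, label: str) -> float:
        """Total duration in seconds carrying ``label``."""
        return float(sum(e - s for s, e in self.intervals(label)))

    def sample_mask(self, label: str, n: int, fs: float = FS_ANALYSIS) -> np.ndarray:
        """Boolean mask over ``n`` samples at ``fs`` for the labeled intervals."""
        mask = np.zeros(n, dtype=bool)
        for s, e in self.intervals(label):
            i0 = max(0, int(round(s * fs)))
            i1 = min(n, int(round(e * fs)))
            mask[i0:i1] = True
        return mask

    def subset(self, label: str) -> "EpochSet":
        return EpochSet(
            [(s, e, lab) for s, e, lab in self._intervals if lab == label],
            self.duration,
            complete=False,
        )


# ---------------------------------------------------------------------------
# filtering primitives
# ---------------------------------------------------------------------------

def zero_phase_filter(
    x: np.ndarray,
    fs: float,
    cutoff,
    btype: str = "lowpass",
    order: int = 4,
) -> np.ndarray:
    """4-pole Butterworth applied forward and reverse (zero net phase).

    ``cutoff`` is a scalar for low/high-pass or a (low, high) pair for a
    band-pass.  The two passes square the magnitude response, so the
    effective amplitude gain is |H(f)|^2 of the one-way filter.
    """
    nyq = fs / 2.0
    wn = np.atleast_1d(np.asarray(cutoff, dtype=float)) / nyq
    if np.any(wn <= 0) or np.any(wn >= 1):
        raise ValueError(f"cutoff {cutoff} Hz not inside (0, {nyq}) Hz")
    sos = signal.butter(order, wn if wn.size > 1 else wn[0], btype=btype, output="sos")
    return signal.sosfiltfilt(sos, x)


def preprocess_trace(trace: WhiskerTrace) -> Kinematics:
    """30 Hz zero-phase low-pass at the native rate, then resample to 1 kHz."""
    if trace.fs <= 60.0:
        raise ValueError(
            f"sampling rate {trace.fs} Hz cannot support a 30 Hz low-pass"
        )
    if trace.duration < 1.0:
        raise ValueError("trace shorter than 1 s")
    x = zero_phase_filter(trace.angle, trace.fs, 30.0, "lowpass")
    if trace.fs == FS_ANALYSIS:
        y = x
    else:
        ratio = Fraction(FS_ANALYSIS / trace.fs).limit_denominator(10000)
        y = signal.resample_poly(x, ratio.numerator, ratio.denominator,
                                 window=("kaiser", 12.0), padtype="line")
    n_target = int(round(trace.duration * FS_ANALYSIS))
    if y.size > n_target:
        y = y[:n_target]
    elif y.size < n_target:
        y = np.pad(y, (0, n_target - y.size), mode="edge")
    return Kinematics(fs=FS_ANALYSIS, angle_f=y)


def compute_setpoint(kin: Kinematics) -> Kinematics:
    """Set point = < 6 Hz component of the filtered angle (zero phase)."""
    sp = zero_phase_filter(kin.angle_f, kin.fs, 6.0, "lowpass")
    return replace(kin, setpoint=sp)


def compute_phase(kin: Kinematics) -> Kinematics:
    """Whisk-cycle phase and amplitude from the 6-30 Hz analytic signal.

    Phase 0 falls at protraction maxima and +/- pi at retraction minima of
    the band-passed angle; the convention follows directly from taking the
    analytic-signal angle of a protraction-positive trace and is pinned by
    a construction test on a synthetic whisk.
    """
    bp = zero_phase_filter(kin.angle_f, kin.fs, (6.0, 30.0), "bandpass")
    analytic = signal.hilbert(bp)
    return replace(kin, phase=np.angle(analytic), amplitude=np.abs(analytic))


def analyze_trace(trace: WhiskerTrace) -> Kinematics:
    """Full preprocessing chain: filter, resample, set point, phase."""
    return compute_phase(compute_setpoint(preprocess_trace(trace)))


# ---------------------------------------------------------------------------
# epoch segmentation
# ---------------------------------------------------------------------------

def _runs(mask: np.ndarray):
    """Half-open index runs where a boolean mask is true."""
    idx = np.flatnonzero(np.diff(np.r_[False, mask, False]))
    return list(zip(idx[0::2], idx[1::2]))


def _merge_runs(runs, max_gap: int):
    merged = []
    for i0, i1 in runs:
        if merged and i0 - merged[-1][1] < max_gap:
            merged[-1] = (merged[-1][0], i1)
        else:
            merged.append((i0, i1))
    return merged


def _extend_run(i0: int, i1: int, above: np.ndarray):
    """Grow a run outward while the envelope stays above the onset floor."""
    while i0 > 0 and above[i0 - 1]:
        i0 -= 1
    n = above.size
    while i1 < n and above[i1]:
        i1 += 1
    return i0, i1


def segment_epochs(
    kin: Kinematics,
    treadmill: np.ndarray | None = None,
    treadmill_fs: float | None = None,
    params: SegmentationParams | None = None,
) -> EpochSet:
    """Label the recording as quiet / whisking / excluded (+ locomotion).

    Whisking is detected where the 6-30 Hz amplitude envelope exceeds the
    whisking threshold, gaps shorter than the merge gap are bridged, and
    bout edges are extended down to the onset floor.  Candidate movement
    events that fail the 500 ms minimum - which subsumes single
    back-and-forth twitches below 5 degrees peak-to-peak - are labeled
    ``excluded`` and enter neither the quiet nor the whisking pool.
    Treadmill activity sustained for at least 400 ms is overlaid as
    ``locomotion``.
    """
    p = params or SegmentationParams()
    if kin.amplitude is None:
        kin = compute_phase(kin)
    env = kin.amplitude
    fs = kin.fs
    n = kin.n
    gap = int(round(p.merge_gap_s * fs))
    above_floor = env >= p.onset_floor_deg

    active = _merge_runs(_runs(env >= p.whisk_threshold_deg), gap)
    active = [_extend_run(i0, i1, above_floor) for i0, i1 in active]
    active = _merge_runs(sorted(active), 1)

    min_bout = int(round(p.min_bout_s * fs))
    label = np.zeros(n, dtype=np.uint8)  # 0 quiet, 1 whisking, 2 excluded
    for i0, i1 in active:
        label[i0:i1] = 1 if (i1 - i0) >= min_bout else 2

    # sub-threshold movement events (e.g. twitches < 5 deg peak-to-peak):
    # anything above the onset floor that did not qualify as whisking.
    weak = _merge_runs(_runs(above_floor), int(round(0.1 * fs)))
    for i0, i1 in weak:
        seg = label[i0:i1]
        seg[seg == 0] = 2

    intervals = []
    for lab_code, lab in ((0, "quiet"), (1, "whisking"), (2, "excluded")):
        for i0, i1 in _runs(label == lab_code):
            intervals.append((i0 / fs, i1 / fs, lab))

    if treadmill is not None:
        tm = np.asarray(treadmill, dtype=float) > 0.5
        tm_fs = treadmill_fs or fs
        min_loc = int(round(p.locomotion_min_s * tm_fs))
        for i0, i1 in _runs(tm):
            if i1 - i0 >= min_loc:
                intervals.append((i0 / tm_fs, min(i1 / tm_fs, n / fs), "locomotion"))

    epochs = EpochSet(intervals, duration=n / fs)
    if epochs.total("quiet") + epochs.total("whisking") == 0:
        import warnings

        warnings.warn("recording entirely excluded; downstream analyses will refuse")
    return epochs


def resting_point(kin: Kinematics, epochs: EpochSet) -> float:
    """Mean whisker angle during non-movement (the tuning-curve reference)."""
    if epochs.total("quiet") < 1.0:
        raise ValueError("need >= 1 s of quiet time to define the resting point")
    mask = epochs.sample_mask("quiet", kin.n, kin.fs)
    return float(np.mean(kin.angle_f[mask]))


def rhythmic_epochs(
    kin: Kinematics,
    epochs: EpochSet,
    params: SegmentationParams | None = None,
):
    """Sustained rhythmic (6-30 Hz) whisking sub-intervals and eligibility.

    Returns ``(rhythmic, eligible)`` where ``rhythmic`` is an
    (incomplete) :class:`EpochSet` of ``rhythmic``-labeled intervals and
    ``eligible`` is true iff the total rhythmic time exceeds 20 s, the
    standard inclusion rule for phase-tuning analysis.
    """
    p = params or SegmentationParams()
    if kin.amplitude is None:
        kin = compute_phase(kin)
    whisk = epochs.sample_mask("whisking", kin.n, kin.fs)
    mask = whisk & (kin.amplitude >= p.rhythm_threshold_deg)
    trim = int(round(p.edge_trim_s * kin.fs))
    mask[:trim] = False
    if trim:
        mask[-trim:] = False
    runs = _merge_runs(_runs(mask), int(round(0.1 * kin.fs)))
    min_run = int(round(p.rhythm_min_s * kin.fs))
    runs = [(i0, i1) for i0, i1 in runs if i1 - i0 >= min_run]
    rhythmic = EpochSet(
        [(i0 / kin.fs, i1 / kin.fs, "rhythmic") for i0, i1 in runs],
        duration=kin.duration,
        complete=False,
    )
    eligible = rhythmic.total("rhythmic") > p.rhythm_total_s
    return rhythmic, eligible
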