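"""Spike-train containers and rate/variability statistics.

Simple-spike (SS) and complex-spike (CS) event times are the inputs;
waveform detection and sorting are upstream of this package.  The
peri-CS histogram is kept as the standard sorting-validation check: a
correctly sorted Purkinje cell shows a ~10 ms SS pause after every CS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinematics import FS_ANALYSIS, EpochSet

RATE_WINDOW_S = 0.1  # rectangular window of the instantaneous-rate estimator


@dataclass
class SpikeTrain:
    """SS and CS event times (seconds, sorted) for one cell."""

    ss_times: np.ndarray
    cs_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    t_start: float = 0.0
    t_end: float | None = None

    def __post_init__(self) -> None:
        self.ss_times = np.asarray(self.ss_times, dtype=float)
        self.cs_times = np.asarray(self.cs_times, dtype=float)
        if self.t_end is None:
            last = max(
                self.ss_times[-1] if self.ss_times.size else 0.0,
                self.cs_times[-1] if self.cs_times.size else 0.0,
            )
            self.t_end = float(last)
        for name, times in (("ss", self.ss_times), ("cs", self.cs_times)):
            if times.size:
                if np.any(np.diff(times) <= 0):
                    raise ValueError(f"{name} times must be strictly increasing")
                if times[0] < self.t_start - 1e-9 or times[-1] > self.t_end + 1e-9:
                    raise ValueError(f"{name} times outside [t_start, t_end]")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class RateSeries:
    """Instantaneous firing rate, one sample per millisecond."""

    fs: float
    rate: np.ndarray
    t_start: float = 0.0

    def __post_init__(self) -> None:
        self.rate = np.asarray(self.rate, dtype=float)
        if np.any(self.rate < -1e-9):
            raise ValueError("rate must be non-negative")

    @property
    def n(self) -> int:
        return self.rate.size

    @property
    def times(self) -> np.ndarray:
        return self.t_start + np.arange(self.n) / self.fs


def instantaneous_rate(
    train: SpikeTrain, fs: float = FS_ANALYSIS, window: float = RATE_WINDOW_S
) -> RateSeries:
    """Moving-average SS rate: centered 100 ms boxcar stepped at 1 ms.

    At the recording edges the boxcar is truncated and the count is
    normalized by the covered window length, so a constant-rate train
    stays flat all the way to the edges.
    """
    n = int(round(train.duration * fs))
    counts = np.zeros(n)
    if train.ss_times.size:
        idx = np.floor((train.ss_times - train.t_start) * fs + 1e-9).astype(int)
        np.add.at(counts, np.clip(idx, 0, n - 1), 1.0)
    w = int(round(window * fs))
    kernel = np.ones(w)
    num = np.convolve(counts, kernel, mode="same")
    cover = np.convolve(np.ones(n), kernel, mode="same") / fs  # seconds in window
    return RateSeries(fs=fs, rate=num / cover, t_start=train.t_start)


def epoch_rate(train: SpikeTrain, interval) -> float:
    """Spike count in ``[start, end)`` divided by the epoch duration."""
    start, end = float(interval[0]), float(interval[1])
    if end <= start:
        raise ValueError("epoch must have positive duration")
    if start < train.t_start - 1e-9 or end > train.t_end + 1e-9:
        raise ValueError("epoch outside the recording")
    count = np.searchsorted(train.ss_times, end) - np.searchsorted(
        train.ss_times, start
    )
    return float(count) / (end - start)


def epoch_rates(train: SpikeTrain, epochs: EpochSet, label: str) -> np.ndarray:
    """Per-epoch rates for every interval carrying ``label``."""
    return np.array([epoch_rate(train, iv) for iv in epochs.intervals(label)])


def pooled_isis(train: SpikeTrain, epochs: EpochSet, label: str) -> np.ndarray:
    """ISIs pooled over the labeled epochs; intervals spanning an epoch
    boundary are discarded rather than truncated."""
    isis = []
    for s, e in epochs.intervals(label):
        i0 = np.searchsorted(train.ss_times, s)
        i1 = np.searchsorted(train.ss_times, e)
        if i1 - i0 >= 2:
            isis.append(np.diff(train.ss_times[i0:i1]))
    return np.concatenate(isis) if isis else np.empty(0)


def isi_cv(train: SpikeTrain, epochs: EpochSet, label: str, min_isis: int = 10):
    """Coefficient of variation (SD/mean) of within-epoch ISIs.

    Returns ``(cv, isis)``; ``cv`` is NaN when fewer than ``min_isis``
    intervals are available (flagged insufficient).
    """
    isis = pooled_isis(train, epochs, label)
    if isis.size < min_isis:
        return float("nan"), isis
    return float(np.std(isis) / np.mean(isis)), isis


@dataclass
class PeriCSResult:
    """SS counts around CS times and the post-CS pause estimate."""

    bin_edges: np.ndarray  # s, relative to the CS
    counts: np.ndarray
    pause_s: float
    n_cs: int
    valid: bool            # pause >= 8 ms: sorting-validation pass
    flagged: bool          # too few CS (or no SS) to judge


def peri_cs_histogram(
    train: SpikeTrain,
    half_window: float = 0.05,
    bin_s: float = 0.001,
    min_cs: int = 20,
) -> PeriCSResult:
    """SS histogram in +/-50 ms around each CS and the post-CS pause.

    The pause is the longest run of empty 1 ms bins starting at lag 0; a
    clean Purkinje-cell sort shows ~10 ms (validation passes at >= 8 ms).
    """
    edges = np.arange(-half_window, half_window + bin_s / 2, bin_s)
    counts = np.zeros(edges.size - 1)
    for c in train.cs_times:
        rel = train.ss_times - c
        sel = rel[(rel >= -half_window) & (rel < half_window)]
        counts += np.histogram(sel, bins=edges)[0]
    zero_bin = np.searchsorted(edges, 0.0)
    pause_bins = 0
    for c in counts[zero_bin:]:
        if c == 0:
            pause_bins += 1
        else:
            break
    flagged = train.cs_times.size < min_cs or train.ss_times.size == 0
    pause = pause_bins * bin_s
    return PeriCSResult(
        bin_edges=edges,
        counts=counts,
        pause_s=pause,
        n_cs=int(train.cs_times.size),
        valid=(pause >= 0.008) and not flagged,
        flagged=flagged,
    )
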