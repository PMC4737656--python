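"""Phase tuning within rhythmic whisking.

Spike phases (the Hilbert phase of the 6-30 Hz band at each spike time)
are histogrammed into 20 bins over (-pi, pi] and normalized by the time
spent in each bin, giving a firing rate per phase bin.  The modulation
depth is (max - min) / mean of the bin rates.  Phase tuning is tested by
a Kuiper test between the spike-time phase sample and the all-time
(full-grid) phase sample.  Conditional on the whisking trajectory,
spikes of an untuned cell are Poisson times, so their phases are iid
draws from the trajectory's own phase distribution; the grid sample
estimates exactly that distribution and therefore enters the test as a
reference population (effective n = number of spikes), with spike
phases circle-interpolated between grid samples to avoid exact ties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinematics import EpochSet, Kinematics
from .spikes import SpikeTrain
from .stats import kuiper_two_sample

N_BINS = 20
ALPHA = 0.05


@dataclass
class PhaseTuning:
    bin_centers: np.ndarray      # rad, 20 bins over (-pi, pi]
    rate: np.ndarray             # Hz per bin
    occupancy: np.ndarray        # s per bin
    modulation_depth: float | None
    pref_phase: float | None     # rad, circular mean of spike phases
    pref_phase_argmax: float | None
    p_kuiper: float | None
    n_spikes: int
    eligible: bool
    rhythmic_time_s: float


def _phase_lookup(times, kin: Kinematics):
    """Phase at event times by 1 ms grid lookup (consistent with the
    grid-sampled occupancy normalization)."""
    idx = np.clip((np.asarray(times) * kin.fs).astype(int), 0, kin.n - 1)
    return kin.phase[idx]


def _phase_at(times, kin: Kinematics):
    """Phase at event times, interpolated on the unit circle between the
    1 ms grid samples (avoids exact ties with the grid itself; used by
    the Kuiper test, whose reference is the grid sample)."""
    t = np.asarray(times) * kin.fs
    i0 = np.clip(t.astype(int), 0, kin.n - 1)
    i1 = np.minimum(i0 + 1, kin.n - 1)
    frac = np.clip(t - i0, 0.0, 1.0)
    z = (1 - frac) * np.exp(1j * kin.phase[i0]) + frac * np.exp(1j * kin.phase[i1])
    return np.angle(z)


def _spikes_in(times: np.ndarray, intervals):
    sel = np.zeros(times.size, dtype=bool)
    for s, e in intervals:
        sel |= (times >= s) & (times < e)
    return times[sel]


def phase_histogram(
    train: SpikeTrain,
    kin: Kinematics,
    rhythmic: EpochSet,
) -> PhaseTuning:
    """Occupancy-normalized phase histogram of SS firing.

    Requires phase-tuning eligibility (> 20 s of rhythmic whisking);
    ineligible cells are refused with an eligibility report.
    """
    if kin.phase is None:
        raise ValueError("kinematics must carry phase")
    total = rhythmic.total("rhythmic")
    edges = np.linspace(-np.pi, np.pi, N_BINS + 1)
    centers = edges[:-1] + np.diff(edges) / 2
    intervals = rhythmic.intervals("rhythmic")

    mask = rhythmic.sample_mask("rhythmic", kin.n, kin.fs)
    occ_counts = np.histogram(kin.phase[mask], bins=edges)[0]
    occupancy = occ_counts / kin.fs

    ss = _spikes_in(train.ss_times, intervals)
    counts = np.histogram(
        _phase_lookup(ss, kin), bins=edges
    )[0] if ss.size else np.zeros(N_BINS)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(occupancy > 0, counts / occupancy, np.nan)

    pref = None
    if ss.size:
        ph = _phase_lookup(ss, kin)
        pref = float(np.angle(np.mean(np.exp(1j * ph))))
    argmax = float(centers[np.nanargmax(rate)]) if np.any(~np.isnan(rate)) else None

    return PhaseTuning(
        bin_centers=centers, rate=rate, occupancy=occupancy,
        modulation_depth=None, pref_phase=pref, pref_phase_argmax=argmax,
        p_kuiper=None, n_spikes=int(ss.size),
        eligible=True, rhythmic_time_s=float(total),
    )


def modulation_depth(tuning: PhaseTuning) -> float:
    """(max rate - min rate) / mean rate over the 20 phase bins."""
    r = tuning.rate
    if np.any(np.isnan(r)):
        raise ValueError("modulation depth requires all phase bins occupied")
    mean = r.mean()
    if mean == 0:
        raise ValueError("zero mean rate: modulation depth undefined")
    return float((r.max() - r.min()) / mean)


def kuiper_phase_test(
    train: SpikeTrain,
    kin: Kinematics,
    rhythmic: EpochSet,
    subsample_s: float = 0.001,
    min_spikes: int = 100,
) -> float:
    """Two-sample Kuiper p: spike-time phases vs (subsampled) all-time phases."""
    if kin.phase is None:
        raise ValueError("kinematics must carry phase")
    intervals = rhythmic.intervals("rhythmic")
    ss = _spikes_in(train.ss_times, intervals)
    if ss.size < min_spikes:
        return float("nan")
    spike_ph = _phase_at(ss, kin)
    mask = rhythmic.sample_mask("rhythmic", kin.n, kin.fs)
    step = max(int(round(subsample_s * kin.fs)), 1)
    all_ph = kin.phase[mask][::step]
    # the all-time sample estimates the null (occupancy) distribution
    # itself, so it enters as a reference population, not an iid sample
    _, p = kuiper_two_sample(spike_ph, all_ph, b_is_reference=True)
    return p


def phase_report(
    train: SpikeTrain,
    kin: Kinematics,
    rhythmic: EpochSet,
    eligible: bool,
) -> PhaseTuning:
    """Histogram, depth and Kuiper test in one record; refuses ineligible cells."""
    if not eligible:
        return PhaseTuning(
            bin_centers=np.empty(0), rate=np.empty(0), occupancy=np.empty(0),
            modulation_depth=None, pref_phase=None, pref_phase_argmax=None,
            p_kuiper=None, n_spikes=0, eligible=False,
            rhythmic_time_s=rhythmic.total("rhythmic"),
        )
    tuning = phase_histogram(train, kin, rhythmic)
    if not np.any(np.isnan(tuning.rate)) and tuning.rate.mean() > 0:
        tuning.modulation_depth = modulation_depth(tuning)
    tuning.p_kuiper = kuiper_phase_test(train, kin, rhythmic)
    return tuning
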