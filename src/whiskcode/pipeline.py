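"""Per-cell end-to-end analysis: one call from raw trace + spikes to a report."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import encoding, kinematics, latency, modulation, phase, spikes
from .decoding import DecodingResult, decode_session
from .encoding import EncodingFit, TuningCurve
from .kinematics import EpochSet, Kinematics, WhiskerTrace
from .latency import LatencyResult
from .modulation import ModulationResult
from .phase import PhaseTuning
from .spikes import PeriCSResult, RateSeries, SpikeTrain


@dataclass
class CellReport:
    """Everything the pipeline computes for one recorded/simulated cell."""

    kin: Kinematics
    epochs: EpochSet
    rate: RateSeries
    resting_point: float | None
    sort_check: PeriCSResult
    modulation: ModulationResult
    latency: LatencyResult | None
    curve: TuningCurve | None
    fit: EncodingFit | None
    phase: PhaseTuning | None
    decoding: DecodingResult | None


def analyze_cell(
    trace: WhiskerTrace,
    train: SpikeTrain,
    treadmill: np.ndarray | None = None,
    seg_params: kinematics.SegmentationParams | None = None,
    decode: bool = True,
) -> CellReport:
    """Run the full analysis chain, skipping stages whose eligibility or
    precondition fails (the corresponding report fields are None)."""
    kin = kinematics.analyze_trace(trace)
    epochs = kinematics.segment_epochs(kin, treadmill=treadmill,
                                       treadmill_fs=trace.fs, params=seg_params)
    rate = spikes.instantaneous_rate(train)
    try:
        rest = kinematics.resting_point(kin, epochs)
    except ValueError:
        rest = None
    sort_check = spikes.peri_cs_histogram(train)
    mod = modulation.modulation_report(train, epochs)

    lat = None
    onsets = [s for s, _ in epochs.intervals("whisking")]
    if mod.direction != "none" and len(onsets) >= 5:
        try:
            lat = latency.xcorr_latency(rate, kin, onsets)
        except ValueError:
            lat = None

    curve = fit = None
    try:
        lag = lat.latency_s if (lat and lat.latency_s is not None) else 0.0
        curve = encoding.tuning_curve(train, kin, epochs, lag_s=lag)
        fit = encoding.fit_linear_encoding(curve)
        if fit.significant:
            fit = encoding.encoding_range_stats(curve, fit, kin, epochs)
    except ValueError:
        pass

    rhythmic, eligible = kinematics.rhythmic_epochs(kin, epochs, seg_params)
    ph = phase.phase_report(train, kin, rhythmic, eligible)

    dec = None
    if decode:
        try:
            dec = decode_session(rate, kin)
        except ValueError:
            dec = None

    return CellReport(
        kin=kin, epochs=epochs, rate=rate, resting_point=rest,
        sort_check=sort_check, modulation=mod, latency=lat,
        curve=curve, fit=fit, phase=ph, decoding=dec,
    )
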