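"""Plain-text readers/writers for session bundles and analysis products."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kinematics import EpochSet, Kinematics, WhiskerTrace
from .spikes import RateSeries, SpikeTrain


def write_trace(path, trace: WhiskerTrace) -> None:
    pd.DataFrame({"time_s": trace.times, "angle_deg": trace.angle}).to_csv(
        path, index=False
    )


def read_trace(path) -> WhiskerTrace:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    fs = 1.0 / np.median(np.diff(t))
    return WhiskerTrace(fs=float(round(fs, 6)), angle=df["angle_deg"].to_numpy())


def write_spikes(path, train: SpikeTrain) -> None:
    rows = [(t, "SS") for t in train.ss_times] + [(t, "CS") for t in train.cs_times]
    rows.sort()
    pd.DataFrame(rows, columns=["time_s", "label"]).to_csv(path, index=False)


def read_spikes(path, t_start: float = 0.0, t_end: float | None = None) -> SpikeTrain:
    df = pd.read_csv(path)
    ss = np.sort(df.loc[df["label"] == "SS", "time_s"].to_numpy())
    cs = np.sort(df.loc[df["label"] == "CS", "time_s"].to_numpy())
    return SpikeTrain(ss_times=ss, cs_times=cs, t_start=t_start, t_end=t_end)


def write_kinematics(path, kin: Kinematics) -> None:
    cols = {"time_s": kin.times, "angle_deg": kin.angle_f}
    if kin.setpoint is not None:
        cols["setpoint_deg"] = kin.setpoint
    if kin.phase is not None:
        cols["phase_rad"] = kin.phase
    if kin.amplitude is not None:
        cols["amplitude_deg"] = kin.amplitude
    pd.DataFrame(cols).to_csv(path, index=False)


def read_kinematics(path) -> Kinematics:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    fs = 1.0 / np.median(np.diff(t))
    return Kinematics(
        fs=float(round(fs, 6)),
        angle_f=df["angle_deg"].to_numpy(),
        setpoint=df["setpoint_deg"].to_numpy() if "setpoint_deg" in df else None,
        phase=df["phase_rad"].to_numpy() if "phase_rad" in df else None,
        amplitude=df["amplitude_deg"].to_numpy() if "amplitude_deg" in df else None,
    )


def write_epochs(path, epochs: EpochSet) -> None:
    """BED-like 3-column text: start_s  end_s  label."""
    with open(path, "w") as fh:
        for s, e, lab in epochs:
            fh.write(f"{s:.6f}\t{e:.6f}\t{lab}\n")


def read_epochs(path, duration: float | None = None,
                complete: bool = True) -> EpochSet:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                s, e, lab = line.split()
                rows.append((float(s), float(e), lab))
    if duration is None:
        duration = max(e for _, e, _ in rows)
    return EpochSet(rows, duration=duration, complete=complete)


def write_rates(path, rate: RateSeries) -> None:
    pd.DataFrame({"time_s": rate.times, "rate_hz": rate.rate}).to_csv(
        path, index=False
    )


def read_rates(path) -> RateSeries:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    fs = 1.0 / np.median(np.diff(t))
    return RateSeries(fs=float(round(fs, 6)), rate=df["rate_hz"].to_numpy(),
                      t_start=float(t[0]))


def write_truth(path, truth: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(truth), fh, sort_keys=False)


def read_truth(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(_plain(obj), indent=2))


def _plain(obj):
    """Recursively convert numpy scalars/arrays and tuples for YAML/JSON."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj


def save_session(out_dir, session) -> None:
    """Write a simulated session bundle (trace, spikes, truth sidecar)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_trace(out / "trace.csv", session.trace)
    write_spikes(out / "spikes.csv", session.spikes)
    pd.DataFrame(
        {"time_s": session.trace.times, "treadmill": session.treadmill}
    ).to_csv(out / "treadmill.csv", index=False)
    write_truth(out / "truth.yaml", session.truth)
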