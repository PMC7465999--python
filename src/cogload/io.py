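"""On-disk session layout: EDF physiology, CSV vehicular data, JSON truth.

One participant's session is three files in a directory:

* ``<id>.edf`` — EEG/EOG/ECG/GSR/respiration channels at their native
  rates in a single EDF file,
* ``<id>_vehicular.csv`` — columns time_s, latpos_m, latspeed_mps,
  swa_deg, yaw_deg, yawrate_dps, landep_flag at the vehicular rate,
* ``<id>_truth.json`` — scripted event schedule and injected event
  times (the ground truth used by oracle tests),

plus one shared ``events.csv`` (event_start_s, scenario, task,
participant) across the cohort.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .edf import EdfSignal, read_edf, write_edf
from .preprocessing import MultimodalRecording
from .synthetic import EventTruth, GroundTruth

__all__ = ["write_session", "read_session", "write_events_csv", "read_events_csv",
           "write_ground_truth", "read_ground_truth"]

_VEH_COLUMNS = ["latpos_m", "latspeed_mps", "swa_deg", "yaw_deg", "yawrate_dps",
                "landep_flag"]


def write_session(recording: MultimodalRecording, out_dir, truth: GroundTruth | None = None) -> dict:
    """Write one session; returns {kind: path} for the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pid = recording.participant_id or "anon"

    signals = []
    for name, data in recording.channels.items():
        if name.startswith("VEH "):
            continue
        dim = "uV" if name.startswith(("EEG", "EOG")) else (
            "mV" if name == "ECG" else ("uS" if name == "GSR" else "au")
        )
        signals.append(EdfSignal(label=name, sample_rate=recording.rates[name],
                                 data=data, physical_dimension=dim))
    edf_path = out_dir / f"{pid}.edf"
    write_edf(edf_path, signals, patient_id=pid, recording_id="synthetic session")

    fs_veh = recording.rates["VEH swa_deg"]
    n = len(recording.channels["VEH swa_deg"])
    veh = pd.DataFrame({"time_s": np.arange(n) / fs_veh})
    for col in _VEH_COLUMNS:
        veh[col] = recording.channels[f"VEH {col}"]
    veh_path = out_dir / f"{pid}_vehicular.csv"
    veh.to_csv(veh_path, index=False)

    paths = {"edf": str(edf_path), "vehicular": str(veh_path)}
    if truth is not None:
        truth_path = out_dir / f"{pid}_truth.json"
        write_ground_truth(truth, truth_path)
        paths["truth"] = str(truth_path)
    return paths


def read_session(out_dir, participant_id: str, veh_rate: float = 10.0) -> MultimodalRecording:
    """Read a session written by :func:`write_session`."""
    out_dir = Path(out_dir)
    channels: dict[str, np.ndarray] = {}
    rates: dict[str, float] = {}
    for sig in read_edf(out_dir / f"{participant_id}.edf"):
        channels[sig.label] = sig.data
        rates[sig.label] = sig.sample_rate
    veh = pd.read_csv(out_dir / f"{participant_id}_vehicular.csv")
    for col in _VEH_COLUMNS:
        channels[f"VEH {col}"] = veh[col].to_numpy(dtype=float)
        rates[f"VEH {col}"] = veh_rate
    return MultimodalRecording(channels=channels, rates=rates,
                               participant_id=participant_id)


def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "participant_id": truth.participant_id,
        "events": [
            {
                "start_s": e.start_s,
                "scenario": e.scenario,
                "task": e.task,
                "blink_times": np.asarray(e.blink_times).tolist(),
                "r_peak_times": np.asarray(e.r_peak_times).tolist(),
                "gsr_peak_times": np.asarray(e.gsr_peak_times).tolist(),
                "swa_reversal_times": np.asarray(e.swa_reversal_times).tolist(),
            }
            for e in truth.events
        ],
    }
    Path(path).write_text(json.dumps(payload))


def read_ground_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    events = [
        EventTruth(
            start_s=e["start_s"],
            scenario=e["scenario"],
            task=e["task"],
            blink_times=np.asarray(e["blink_times"]),
            r_peak_times=np.asarray(e["r_peak_times"]),
            gsr_peak_times=np.asarray(e["gsr_peak_times"]),
            swa_reversal_times=np.asarray(e["swa_reversal_times"]),
        )
        for e in payload["events"]
    ]
    return GroundTruth(participant_id=payload["participant_id"], events=events)


def write_events_csv(rows: list[tuple[float, str, str, str]], path) -> None:
    """rows = (event_start_s, scenario, task, participant)."""
    pd.DataFrame(
        rows, columns=["event_start_s", "scenario", "task", "participant"]
    ).to_csv(path, index=False)


def read_events_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
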