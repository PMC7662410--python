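"""Plain-text persistence: two-column signal CSVs with JSON sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import RawRecording, StimulusSchedule

__all__ = ["write_recording", "read_recording", "list_subjects"]


def write_recording(directory, subject_id: str, rec: RawRecording) -> None:
    """One ``<subject>_<channel>.csv`` per channel plus ``<subject>.json``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, samples in rec.channels.items():
        t = np.arange(len(samples)) / rec.fs_hz
        pd.DataFrame({"time_s": t, "value": samples}).to_csv(
            directory / f"{subject_id}_{name}.csv", index=False)
    sidecar = {
        "subject_id": subject_id,
        "fs_hz": rec.fs_hz,
        "channels": sorted(rec.channels),
        "units": rec.units,
        "schedule": rec.schedule.to_jsonable() if rec.schedule else None,
    }
    (directory / f"{subject_id}.json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True))


def read_recording(directory, subject_id: str) -> RawRecording:
    directory = Path(directory)
    sidecar = json.loads((directory / f"{subject_id}.json").read_text())
    channels = {}
    for name in sidecar["channels"]:
        df = pd.read_csv(directory / f"{subject_id}_{name}.csv")
        channels[name] = df["value"].to_numpy(dtype=float)
    schedule = (StimulusSchedule.from_jsonable(sidecar["schedule"])
                if sidecar.get("schedule") else None)
    return RawRecording(channels=channels, fs_hz=float(sidecar["fs_hz"]),
                        schedule=schedule, units=sidecar.get("units", {}))


def list_subjects(directory) -> list[str]:
    directory = Path(directory)
    return sorted(p.stem for p in directory.glob("*.json"))
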