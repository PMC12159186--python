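"""HDF5 / CSV / JSON persistence for experiments and results."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import GazeTrace, StimulusLayout, TaggedRecording
from .dics import LeadField


def save_recording(rec: TaggedRecording, path) -> None:
    """Write a recording to HDF5 (datasets /data, /ref, /time, /sensors)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data, compression="gzip")
        f.create_dataset("ref", data=rec.ref, compression="gzip")
        f.create_dataset("time", data=rec.time)
        f.create_dataset("sensors",
                         data=np.array(rec.sensor_labels, dtype="S"))
        f.create_dataset("candidate_sensors",
                         data=np.array(rec.candidate_sensors, dtype="S"))
        f.attrs["fs"] = rec.fs
        f.attrs["ref_freqs"] = list(rec.ref_freqs)


def load_recording(path) -> TaggedRecording:
    with h5py.File(path, "r") as f:
        return TaggedRecording(
            data=f["data"][()],
            ref=f["ref"][()],
            time=f["time"][()],
            fs=float(f.attrs["fs"]),
            ref_freqs=tuple(float(x) for x in f.attrs["ref_freqs"]),
            sensor_labels=[s.decode() for s in f["sensors"][()]],
            candidate_sensors=[s.decode() for s in f["candidate_sensors"][()]],
        )


def save_trials(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False)


def load_trials(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"condition": str, "target_colour": str,
                                    "response": str})


def save_layouts(layouts, path) -> None:
    payload = [{
        "positions": lay.positions.tolist(),
        "colours": lay.colours.tolist(),
        "is_target": lay.is_target.tolist(),
    } for lay in layouts]
    Path(path).write_text(json.dumps(payload))


def load_layouts(path):
    payload = json.loads(Path(path).read_text())
    return [StimulusLayout(positions=np.array(p["positions"]),
                           colours=np.array(p["colours"]),
                           is_target=np.array(p["is_target"]))
            for p in payload]


def save_gaze(gazes, path) -> None:
    with h5py.File(path, "w") as f:
        for i, tr in enumerate(gazes):
            g = f.create_group(f"trial{i:04d}")
            g.create_dataset("x", data=tr.x)
            g.create_dataset("y", data=tr.y)
            g.attrs["fs"] = tr.fs
            g.create_dataset("saccades", data=np.array(tr.saccade_events,
                                                       dtype=float).reshape(-1, 2))
            g.create_dataset("blinks", data=np.array(tr.blink_events,
                                                     dtype=float).reshape(-1, 2))


def load_gaze(path):
    out = []
    with h5py.File(path, "r") as f:
        for key in sorted(f.keys()):
            g = f[key]
            out.append(GazeTrace(
                x=g["x"][()], y=g["y"][()], fs=float(g.attrs["fs"]),
                saccade_events=[tuple(r) for r in g["saccades"][()]],
                blink_events=[tuple(r) for r in g["blinks"][()]],
            ))
    return out


def save_leadfield(lf: LeadField, path) -> None:
    """Lead field as HDF5 (datasets /L, /positions)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("L", data=lf.L)
        f.create_dataset("positions", data=lf.positions)


def load_leadfield(path) -> LeadField:
    with h5py.File(path, "r") as f:
        return LeadField(L=f["L"][()], positions=f["positions"][()])
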