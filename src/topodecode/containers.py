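"""HDF5 containers for recordings and epoch sets.

One file per subject.  Recording schema::

    /eeg                  float32, channels x samples, microvolts
    /events/<column>      one dataset per event-table column
    /kinematics/position  float64, 2 x samples, meters
    /kinematics/velocity  float64, samples, m/s
    attrs: sampling_rate, layout_name, subject_id, seed

Epoch-set schema::

    /trials               float32, n x channels x T
    /labels               int64, n
    /channel_names        UTF-8 strings
    attrs: task, window, K, class_names, sampling_rate, subject_id

Round-trips are bit-exact: arrays are stored without compression or
scaling and string columns as fixed UTF-8.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .preprocess import LabelledEpochSet
from .synth import KinematicsTrace, SubjectRecording

__all__ = [
    "save_recording",
    "load_recording",
    "save_epochs",
    "load_epochs",
]

_STR = h5py.string_dtype(encoding="utf-8")


def save_recording(
    recording: SubjectRecording, path: str | Path, seed: int | None = None
) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("eeg", data=recording.eeg)
        ev = f.create_group("events")
        for col in recording.events.columns:
            data = recording.events[col].to_numpy()
            if data.dtype == object:
                data = data.astype(_STR)
            ev.create_dataset(col, data=data)
        kin = f.create_group("kinematics")
        kin.create_dataset("position", data=recording.kinematics.position_xy)
        kin.create_dataset("velocity", data=recording.kinematics.velocity)
        f.attrs["sampling_rate"] = recording.sampling_rate
        f.attrs["layout_name"] = recording.layout_name
        f.attrs["subject_id"] = recording.subject_id
        if seed is not None:
            f.attrs["seed"] = int(seed)


def load_recording(path: str | Path) -> SubjectRecording:
    with h5py.File(path, "r") as f:
        eeg = f["eeg"][()]
        cols = {}
        for col, ds in f["events"].items():
            vals = ds[()]
            if vals.dtype.kind in ("O", "S"):
                vals = np.array([v.decode() if isinstance(v, bytes) else v for v in vals], dtype=object)
            cols[col] = vals
        events = pd.DataFrame(cols)[list(f["events"].keys())]
        fs = float(f.attrs["sampling_rate"])
        kin = KinematicsTrace(
            position_xy=f["kinematics/position"][()],
            velocity=f["kinematics/velocity"][()],
            sampling_rate=fs,
        )
        rec = SubjectRecording(
            subject_id=str(f.attrs["subject_id"]),
            eeg=eeg,
            sampling_rate=fs,
            events=events,
            kinematics=kin,
            layout_name=str(f.attrs["layout_name"]),
        )
    # canonical column order if all expected columns are present
    expected = ["stimulus_sample", "movement_onset_sample", "mode", "direction", "true_rt"]
    if set(expected) <= set(rec.events.columns):
        rec.events = rec.events[expected]
    return rec


def save_epochs(epochs: LabelledEpochSet, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("trials", data=epochs.trials)
        f.create_dataset("labels", data=epochs.labels.astype(np.int64))
        f.create_dataset(
            "channel_names", data=np.array(epochs.channel_names, dtype=_STR)
        )
        f.attrs["task"] = epochs.task
        f.attrs["window"] = np.array(epochs.window, dtype=float)
        f.attrs["K"] = int(epochs.K)
        f.attrs["class_names"] = np.array(epochs.class_names, dtype=_STR)
        f.attrs["sampling_rate"] = float(epochs.sampling_rate)
        f.attrs["subject_id"] = epochs.subject_id


def load_epochs(path: str | Path) -> LabelledEpochSet:
    with h5py.File(path, "r") as f:
        return LabelledEpochSet(
            trials=f["trials"][()],
            labels=f["labels"][()],
            K=int(f.attrs["K"]),
            class_names=tuple(
                s.decode() if isinstance(s, bytes) else str(s)
                for s in f.attrs["class_names"]
            ),
            channel_names=tuple(
                s.decode() if isinstance(s, bytes) else str(s)
                for s in f["channel_names"][()]
            ),
            subject_id=str(f.attrs["subject_id"]),
            sampling_rate=float(f.attrs["sampling_rate"]),
            window=tuple(float(v) for v in f.attrs["window"]),
            task=str(f.attrs["task"]),
        )
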