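"""HDF5 / CSV / JSON persistence for recordings and ground truth.

Layout: LFP series under ``/lfp/<structure>`` with root attributes ``fs``,
``rat_id``, ``session_label`` and ``seed``; the trial-event table travels as
a CSV sidecar and the simulator ground truth as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .simulate import GroundTruth, SessionRecording, TrialTable

__all__ = [
    "write_recording",
    "read_recording",
    "write_ground_truth",
    "read_ground_truth",
]


def write_recording(recording: SessionRecording, h5_path, events_path=None) -> None:
    h5_path = Path(h5_path)
    with h5py.File(h5_path, "w") as f:
        grp = f.create_group("lfp")
        for name, series in recording.channels.items():
            grp.create_dataset(name, data=np.asarray(series, dtype=np.float64))
        f.attrs["fs"] = recording.fs
        f.attrs["rat_id"] = recording.rat_id
        f.attrs["session_label"] = recording.session_label
        f.attrs["seed"] = recording.seed
        f.attrs["channel_order"] = list(recording.channels)
    if events_path is None:
        events_path = h5_path.with_suffix(".events.csv")
    recording.events.to_csv(events_path)


def read_recording(h5_path, events_path=None) -> SessionRecording:
    h5_path = Path(h5_path)
    if events_path is None:
        events_path = h5_path.with_suffix(".events.csv")
    events = TrialTable.from_csv(events_path)
    with h5py.File(h5_path, "r") as f:
        order = [str(s) for s in f.attrs.get("channel_order", list(f["lfp"]))]
        channels = {name: f["lfp"][name][...] for name in order}
        return SessionRecording(
            channels=channels,
            fs=float(f.attrs["fs"]),
            events=events,
            rat_id=str(f.attrs.get("rat_id", "")),
            session_label=str(f.attrs.get("session_label", "")),
            seed=int(f.attrs.get("seed", 0)),
        )


def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "burst_gains": {s: np.asarray(g).tolist() for s, g in truth.burst_gains.items()},
        "burst_peak_times": np.asarray(truth.burst_peak_times).tolist(),
        "burst_phases": {s: np.asarray(p).tolist() for s, p in truth.burst_phases.items()},
        "pair_offsets": {f"{a}|{b}": list(v) for (a, b), v in truth.pair_offsets.items()},
        "artifact_intervals": {
            s: [list(iv) for iv in ivs] for s, ivs in truth.artifact_intervals.items()
        },
        "latent_performance": np.asarray(truth.latent_performance).tolist(),
        "intended_label": truth.intended_label,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth(path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    return GroundTruth(
        burst_gains={s: np.asarray(g) for s, g in d["burst_gains"].items()},
        burst_peak_times=np.asarray(d["burst_peak_times"]),
        burst_phases={s: np.asarray(p) for s, p in d["burst_phases"].items()},
        pair_offsets={
            tuple(k.split("|")): tuple(v) for k, v in d["pair_offsets"].items()
        },
        artifact_intervals={
            s: [tuple(iv) for iv in ivs] for s, ivs in d["artifact_intervals"].items()
        },
        latent_performance=np.asarray(d["latent_performance"]),
        intended_label=d.get("intended_label", ""),
    )
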