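"""File interfaces: tracking CSV/HDF5, spikes HDF5, WAV audio, truth JSON."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.io import wavfile

from .synthetic import BatTrack, FlightEvent, SpikeTrain, SyntheticSession

__all__ = [
    "write_tracking_csv",
    "read_tracking_csv",
    "write_tracking_h5",
    "read_tracking_h5",
    "write_flights_csv",
    "write_spikes_h5",
    "read_spikes_h5",
    "write_wav",
    "read_wav",
    "write_truth_json",
]


def write_tracking_csv(session: SyntheticSession, path: str | Path) -> None:
    """Long-format table (bat_id, t, x, y, z) in metres, t in seconds."""
    frames = []
    for tr in session.tracks:
        frames.append(pd.DataFrame({
            "bat_id": tr.bat_id, "t": tr.t,
            "x": tr.pos[:, 0], "y": tr.pos[:, 1], "z": tr.pos[:, 2],
        }))
    pd.concat(frames).to_csv(path, index=False)


def read_tracking_csv(path: str | Path) -> list[BatTrack]:
    df = pd.read_csv(path)
    tracks = []
    for bat_id, g in df.groupby("bat_id"):
        g = g.sort_values("t")
        tracks.append(BatTrack(int(bat_id), g["t"].to_numpy(),
                               g[["x", "y", "z"]].to_numpy()))
    return tracks


def write_tracking_h5(session: SyntheticSession, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        for tr in session.tracks:
            g = f.create_group(f"bat_{tr.bat_id}")
            g.create_dataset("t", data=tr.t)
            g.create_dataset("pos", data=tr.pos)
            if tr.accel_mag is not None:
                g.create_dataset("accel_mag", data=tr.accel_mag)


def read_tracking_h5(path: str | Path) -> list[BatTrack]:
    tracks = []
    with h5py.File(path, "r") as f:
        for name in sorted(f):
            g = f[name]
            acc = g["accel_mag"][:] if "accel_mag" in g else None
            tracks.append(BatTrack(int(name.split("_")[1]), g["t"][:],
                                   g["pos"][:], acc))
    return tracks


def write_flights_csv(flights: list[FlightEvent], path: str | Path) -> None:
    rows = [{
        "bat_id": f.bat_id, "t_takeoff": f.t_takeoff, "t_land": f.t_land,
        "x_takeoff": f.p_takeoff[0], "y_takeoff": f.p_takeoff[1],
        "z_takeoff": f.p_takeoff[2],
        "x_land": f.p_land[0], "y_land": f.p_land[1], "z_land": f.p_land[2],
        "duration": f.duration, "path_cluster": f.path_cluster,
    } for f in flights]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_spikes_h5(spike_trains: list[SpikeTrain], path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        for st in spike_trains:
            f.create_dataset(f"unit_{st.unit_id}", data=st.times)


def read_spikes_h5(path: str | Path) -> list[SpikeTrain]:
    out = []
    with h5py.File(path, "r") as f:
        for name in sorted(f):
            out.append(SpikeTrain(f[name][:], int(name.split("_")[1])))
    return out


def write_wav(audio: np.ndarray, fs: float, path: str | Path) -> None:
    wavfile.write(path, int(fs), np.asarray(audio, dtype=np.float32))


def read_wav(path: str | Path) -> tuple[np.ndarray, float]:
    fs, data = wavfile.read(path)
    return np.asarray(data, dtype=np.float32), float(fs)


def write_truth_json(session: SyntheticSession, path: str | Path) -> None:
    truth = session.truth

    def conv(v):
        if isinstance(v, np.ndarray):
            return v.tolist()
        if isinstance(v, list):
            return [conv(x) for x in v]
        return v

    payload = {k: conv(v) for k, v in truth.items()}
    Path(path).write_text(json.dumps(payload, indent=1, default=str))
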