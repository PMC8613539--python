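"""HDF5/JSON interchange for trajectories, cine series, and experiment runs."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

from .geometry import RadialTrajectory

__all__ = [
    "save_trajectory",
    "load_trajectory",
    "save_manifest",
    "load_manifest",
]


def save_trajectory(traj: RadialTrajectory, path) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("trajectory")
        g.create_dataset("angles_deg", data=traj.angles_deg)
        g.create_dataset("coords", data=traj.coords)
        g.create_dataset("dcf", data=traj.dcf)
        g.attrs["start_index"] = traj.start_index
        g.attrs["n_samples"] = traj.n_samples


def load_trajectory(path) -> RadialTrajectory:
    with h5py.File(path, "r") as f:
        g = f["trajectory"]
        return RadialTrajectory(
            angles_deg=np.asarray(g["angles_deg"]),
            coords=np.asarray(g["coords"]),
            dcf=np.asarray(g["dcf"]),
            start_index=int(g.attrs["start_index"]),
            n_samples=int(g.attrs["n_samples"]),
        )


def save_manifest(entries: Sequence[dict], path) -> None:
    Path(path).write_text(json.dumps(list(entries), indent=2, sort_keys=True))


def load_manifest(path) -> list:
    return json.loads(Path(path).read_text())
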