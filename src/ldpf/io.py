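"""HDF5 containers for fields and trajectories, plus raster export.

Round-trips are lossless for double precision.  Field snapshots store the
raw c grid with its parameters and clock; trajectory containers store the
unwrapped position block with times and metadata.  Small CSV mirrors of
trajectories are available for interoperability with tabular tools.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import h5py
import numpy as np

from .phasefield import FieldState, ModelParams, NormalizedField
from .tracers import TrajectorySet

__all__ = [
    "save_field",
    "load_field",
    "save_normalized_field",
    "load_normalized_field",
    "save_trajectories",
    "load_trajectories",
    "trajectories_to_csv",
    "export_field_png",
    "file_sha256",
]


def _write_attrs(group, mapping):
    for k, v in mapping.items():
        if v is None:
            continue
        if isinstance(v, (np.floating, np.integer)):
            v = v.item()
        group.attrs[k] = v


def save_field(path, state: FieldState, params: ModelParams | None = None,
               seed: int | None = None) -> None:
    """Save a raw field snapshot (c grid, clock, parameters, seed)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("c", data=state.c, track_times=False)
        f.attrs["t"] = state.t
        if seed is not None:
            f.attrs["seed"] = seed
        if state.imp_positions is not None:
            f.create_dataset("imp_positions", data=state.imp_positions, track_times=False)
        if params is not None:
            grp = f.create_group("params")
            _write_attrs(grp, dataclasses.asdict(params))


def load_field(path) -> tuple[FieldState, ModelParams | None]:
    """Load a field snapshot; the generator state is a fresh default rng."""
    with h5py.File(path, "r") as f:
        c = f["c"][...]
        t = float(f.attrs.get("t", 0.0))
        imp = f["imp_positions"][...] if "imp_positions" in f else None
        params = None
        if "params" in f:
            kw = {k: v for k, v in f["params"].attrs.items()}
            kw["N_imp"] = int(kw.get("N_imp", 0))
            kw["n_steps"] = int(kw.get("n_steps", 0))
            kw["L"] = int(kw.get("L", c.shape[0]))
            params = ModelParams(**kw)
    return FieldState(c=c, t=t, imp_positions=imp), params


def save_normalized_field(path, field: NormalizedField) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("cbar", data=field.cbar, track_times=False)
        f.attrs["c_min"] = field.c_min
        f.attrs["c_max"] = field.c_max
        f.attrs["dx"] = field.dx
        f.attrs["threshold"] = field.threshold


def load_normalized_field(path) -> NormalizedField:
    with h5py.File(path, "r") as f:
        return NormalizedField(cbar=f["cbar"][...],
                               c_min=float(f.attrs["c_min"]),
                               c_max=float(f.attrs["c_max"]),
                               dx=float(f.attrs["dx"]),
                               threshold=float(f.attrs["threshold"]))


def save_trajectories(path, traj: TrajectorySet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=traj.times, track_times=False)
        f.create_dataset("positions", data=traj.positions,
                         chunks=(min(1024, traj.n_times), traj.n_particles, 2),
                         track_times=False)
        f.attrs["sampling_interval"] = traj.sampling_interval
        f.attrs["box"] = traj.box
        f.attrs["metadata"] = json.dumps(traj.metadata, default=str)


def load_trajectories(path) -> TrajectorySet:
    with h5py.File(path, "r") as f:
        return TrajectorySet(times=f["times"][...],
                             positions=f["positions"][...],
                             sampling_interval=float(f.attrs["sampling_interval"]),
                             box=float(f.attrs["box"]),
                             metadata=json.loads(f.attrs.get("metadata", "{}")))


def trajectories_to_csv(path, traj: TrajectorySet) -> None:
    """Tidy CSV mirror: time, particle_id, x_unwrapped, y_unwrapped."""
    import pandas as pd
    n_t, n_p, _ = traj.positions.shape
    df = pd.DataFrame({
        "time": np.repeat(traj.times, n_p),
        "particle_id": np.tile(np.arange(n_p), n_t),
        "x_unwrapped": traj.positions[:, :, 0].ravel(),
        "y_unwrapped": traj.positions[:, :, 1].ravel(),
    })
    df.to_csv(path, index=False)


def export_field_png(path, field: NormalizedField) -> None:
    """8-bit raster of cbar with a diverging colormap (Lo red, Ld blue)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    plt.imsave(path, field.cbar.T, cmap="RdBu", vmin=0.0, vmax=1.0, origin="lower")


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
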