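"""Trajectory persistence: HDF5 plus XYZ / CSV interoperability exports."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import h5py
import numpy as np

from .simulation import SimParams, Trajectory

__all__ = ["save_trajectory", "load_trajectory", "export_xyz", "export_tensions_csv"]


def save_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as HDF5 (/params attrs, /frames/{positions,tensions,time})."""
    with h5py.File(path, "w") as h5:
        grp = h5.create_group("params")
        for f in dataclasses.fields(traj.params):
            grp.attrs[f.name] = getattr(traj.params, f.name)
        grp.attrs["replica"] = traj.replica
        frames = h5.create_group("frames")
        frames.create_dataset("positions", data=traj.positions, compression="gzip")
        frames.create_dataset("tensions", data=traj.tensions, compression="gzip")
        frames.create_dataset("time", data=traj.times)


def load_trajectory(path: str | Path) -> Trajectory:
    with h5py.File(path, "r") as h5:
        attrs = dict(h5["params"].attrs)
        replica = int(attrs.pop("replica", 0))
        field_names = {f.name for f in dataclasses.fields(SimParams)}
        kwargs = {}
        for k, v in attrs.items():
            if k not in field_names:
                continue
            if isinstance(v, bytes):
                v = v.decode()
            elif isinstance(v, np.generic):
                v = v.item()
            kwargs[k] = v
        params = SimParams(**kwargs)
        return Trajectory(
            h5["frames/time"][...],
            h5["frames/positions"][...],
            h5["frames/tensions"][...],
            params,
            replica=replica,
        )


def export_xyz(traj: Trajectory, path: str | Path, element: str = "C") -> None:
    """One XYZ model per frame, an element tag per bead (coordinates in nm)."""
    n = traj.positions.shape[1]
    with open(path, "w") as fh:
        for t, pos in zip(traj.times, traj.positions):
            fh.write(f"{n}\n")
            fh.write(f"time={t:.9e} s replica={traj.replica}\n")
            for x, y, z in pos:
                fh.write(f"{element} {x:.4f} {y:.4f} {z:.4f}\n")


def export_tensions_csv(traj: Trajectory, path: str | Path) -> None:
    """CSV sidecar: one row per frame, one column per A2 spring (pN)."""
    n_springs = traj.tensions.shape[1]
    header = "time," + ",".join(f"spring_{i}" for i in range(n_springs))
    data = np.column_stack([traj.times, traj.tensions])
    np.savetxt(path, data, delimiter=",", header=header, comments="")
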