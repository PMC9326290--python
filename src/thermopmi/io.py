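"""Readers and writers for the package's external formats.

Point clouds come in as PLY (via trimesh) or whitespace XYZ; measured
logger series as CSV with columns ``logger_id``, ``time_h`` (or
``timestamp_iso8601``) and ``temp_C``; grids and field snapshots go out
as HDF5; simulated curves as CSV with ``location, time_h, temp_C``.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import trimesh
import yaml

from .errors import InvalidInputError
from .geometry import PointCloud, VoxelGrid
from .matching import MeasuredCurve
from .simulation import CoolingCurve, TemperatureField


def load_point_cloud(path: str | Path, logger_sites: dict[str, list[float]] | None = None) -> PointCloud:
    """Load a PLY or XYZ point cloud; logger sites come from the config sidecar."""
    path = Path(path)
    if path.suffix.lower() == ".ply":
        mesh = trimesh.load(path)
        points = np.asarray(mesh.vertices, dtype=float)
    elif path.suffix.lower() in (".xyz", ".txt"):
        points = np.loadtxt(path, dtype=float)
        if points.ndim != 2 or points.shape[1] < 3:
            raise InvalidInputError(f"{path} does not contain three columns of coordinates")
        points = points[:, :3]
    else:
        raise InvalidInputError(f"unsupported point-cloud format {path.suffix!r}")
    sites = {k: np.asarray(v, dtype=float) for k, v in (logger_sites or {}).items()}
    return PointCloud(points=points, logger_sites=sites)


def write_grid_hdf5(grid: VoxelGrid, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("labels", data=grid.labels, compression="gzip")
        f.create_dataset("body_mask", data=grid.body_mask, compression="gzip")
        f.create_dataset("clamped", data=grid.clamped, compression="gzip")
        f.attrs["cube_size"] = grid.cube_size
        f.attrs["origin"] = grid.origin


def read_grid_hdf5(path: str | Path) -> VoxelGrid:
    with h5py.File(path, "r") as f:
        labels = f["labels"][...]
        clamped = f["clamped"][...]
        return VoxelGrid(dims=labels.shape, cube_size=float(f.attrs["cube_size"]),
                         origin=np.asarray(f.attrs["origin"]), labels=labels,
                         clamped=clamped)


def write_field_snapshots_hdf5(fields: list[TemperatureField], path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        times = np.array([fld.time_h for fld in fields])
        f.create_dataset("time_h", data=times)
        for i, fld in enumerate(fields):
            f.create_dataset(f"temperature/{i:05d}", data=fld.temperatures, compression="gzip")


def write_curves_csv(curves: list[CoolingCurve], path: str | Path) -> None:
    frames = [pd.DataFrame({"location": c.location, "time_h": c.times_h,
                            "temp_C": c.temperatures}) for c in curves]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6f")


def write_measured_curves_csv(curves: list[MeasuredCurve], path: str | Path) -> None:
    frames = [pd.DataFrame({"logger_id": c.location, "time_h": c.relative_times_h,
                            "temp_C": c.temperatures}) for c in curves]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6f")


def read_measured_curves_csv(path: str | Path) -> dict[str, MeasuredCurve]:
    """Parse logger CSV into per-location measured curves.

    Accepts either a ``time_h`` column (hours, arbitrary origin) or ISO
    timestamps in ``timestamp_iso8601``; times are shifted to start at 0
    per logger.  The ambient logger (``logger_id == "ambient"``) is
    returned like any other and separated by the caller.
    """
    df = pd.read_csv(path)
    if "time_h" in df.columns:
        df = df.assign(_t=df["time_h"].astype(float))
        first_stamp = {}
    elif "timestamp_iso8601" in df.columns:
        stamps = pd.to_datetime(df["timestamp_iso8601"])
        df = df.assign(_t=(stamps - stamps.min()).dt.total_seconds() / 3600.0)
        first_stamp = {k: str(v.min()) for k, v in stamps.groupby(df["logger_id"])}
    else:
        raise InvalidInputError("curve CSV needs a time_h or timestamp_iso8601 column")
    out = {}
    for logger_id, sub in df.groupby("logger_id"):
        sub = sub.sort_values("_t")
        t = sub["_t"].to_numpy(dtype=float)
        out[str(logger_id)] = MeasuredCurve(
            location=str(logger_id), relative_times_h=t - t[0],
            temperatures=sub["temp_C"].to_numpy(dtype=float),
            timestamp_of_first_sample=first_stamp.get(logger_id))
    return out


def load_config(path: str | Path) -> dict:
    """Load a JSON or YAML run configuration."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)
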