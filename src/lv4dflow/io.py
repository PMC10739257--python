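"""Readers and writers for the pipeline's on-disk formats.

Conventions stamped into every file: positions in mm, velocity in m/s,
pressure exported in mmHg (1 mmHg = 133.322 Pa), 0-based voxel-centered
grids, time in seconds. HDF5 round-trips are lossless; the legacy-VTK
ASCII structured-points files are float32 visualisation exports.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .grid import FlowField4D, GridSpec, PressureField4D
from .imaging import CameraModel, ImageSequence
from .pod import PODResult
from .tracks import TrackSet

__all__ = [
    "SchemaError",
    "write_tracks_csv", "read_tracks_csv", "write_tracks_h5", "read_tracks_h5",
    "write_flow_h5", "read_flow_h5", "write_pressure_h5", "read_pressure_h5",
    "write_flow_vtk", "read_vtk_structured_points",
    "write_image_sequence", "read_image_sequence",
    "write_pod_h5", "read_pod_h5",
]

SCHEMA_VERSION = 1
_CONVENTION = "0-based voxel-centered; origin + (index + 0.5) * spacing [mm]"


class SchemaError(ValueError):
    """A file does not match the expected column/dataset schema."""


def _stamp(obj, **extra):
    obj.attrs["schema_version"] = SCHEMA_VERSION
    obj.attrs["coordinate_convention"] = _CONVENTION
    obj.attrs["units"] = json.dumps({"position": "mm", "velocity": "m/s",
                                     "pressure": "Pa", "time": "s"})
    for k, v in extra.items():
        if v is not None:
            obj.attrs[k] = v


def _check_schema(f):
    v = f.attrs.get("schema_version")
    if v != SCHEMA_VERSION:
        raise SchemaError(f"unknown schema version {v!r} (expected {SCHEMA_VERSION})")


# ---------------------------------------------------------------------------
# Tracks
# ---------------------------------------------------------------------------

_TRACK_COLUMNS = ["track_id", "t_index", "x_mm", "y_mm", "z_mm", "active"]


def write_tracks_csv(tracks: TrackSet, path) -> None:
    rows = []
    has_vel = tracks.velocity is not None
    has_acc = tracks.acceleration is not None
    for k in range(tracks.n_tracks):
        for t in np.flatnonzero(tracks.active[k]):
            row = {"track_id": int(tracks.ids[k]), "t_index": int(t),
                   "x_mm": tracks.positions[k, t, 0],
                   "y_mm": tracks.positions[k, t, 1],
                   "z_mm": tracks.positions[k, t, 2],
                   "active": 1}
            if has_vel:
                row.update(vx=tracks.velocity[k, t, 0], vy=tracks.velocity[k, t, 1],
                           vz=tracks.velocity[k, t, 2])
            if has_acc:
                row.update(ax=tracks.acceleration[k, t, 0],
                           ay=tracks.acceleration[k, t, 1],
                           az=tracks.acceleration[k, t, 2])
            rows.append(row)
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        fh.write(f"# lv4dflow tracks schema v{SCHEMA_VERSION}; units mm, m/s, m/s^2; "
                 f"time_step_s={tracks.time_step!r}\n")
        df.to_csv(fh, index=False)


def read_tracks_csv(path, time_step: float | None = None) -> TrackSet:
    with open(path) as fh:
        header = fh.readline()
        if header.startswith("#") and "time_step_s=" in header:
            time_step = float(header.split("time_step_s=")[1].strip())
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    missing = [c for c in _TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"track CSV is missing column(s): {', '.join(missing)}")
    if time_step is None:
        raise ValueError("time_step not recorded in file and not provided")
    ids = np.unique(df["track_id"].to_numpy())
    n_steps = int(df["t_index"].max()) + 1
    positions = np.full((len(ids), n_steps, 3), np.nan)
    active = np.zeros((len(ids), n_steps), dtype=bool)
    vel = np.full_like(positions, np.nan) if "vx" in df.columns else None
    acc = np.full_like(positions, np.nan) if "ax" in df.columns else None
    id_map = {tid: k for k, tid in enumerate(ids)}
    for _, row in df.iterrows():
        k, t = id_map[row["track_id"]], int(row["t_index"])
        positions[k, t] = (row["x_mm"], row["y_mm"], row["z_mm"])
        active[k, t] = bool(row["active"])
        if vel is not None:
            vel[k, t] = (row["vx"], row["vy"], row["vz"])
        if acc is not None:
            acc[k, t] = (row["ax"], row["ay"], row["az"])
    return TrackSet(positions, active, time_step, ids=ids, velocity=vel,
                    acceleration=acc)


def write_tracks_h5(tracks: TrackSet, path, seed=None, config_hash=None) -> None:
    with h5py.File(path, "w") as f:
        _stamp(f, time_step_s=tracks.time_step, seed=seed, config_hash=config_hash)
        f.create_dataset("positions", data=tracks.positions, compression="gzip")
        f.create_dataset("active", data=tracks.active, compression="gzip")
        f.create_dataset("ids", data=tracks.ids)
        f.create_dataset("terminated", data=tracks.terminated)
        if tracks.velocity is not None:
            f.create_dataset("velocity", data=tracks.velocity, compression="gzip")
        if tracks.acceleration is not None:
            f.create_dataset("acceleration", data=tracks.acceleration, compression="gzip")


def read_tracks_h5(path) -> TrackSet:
    with h5py.File(path, "r") as f:
        _check_schema(f)
        return TrackSet(
            f["positions"][()], f["active"][()], float(f.attrs["time_step_s"]),
            ids=f["ids"][()], terminated=f["terminated"][()],
            velocity=f["velocity"][()] if "velocity" in f else None,
            acceleration=f["acceleration"][()] if "acceleration" in f else None)


# ---------------------------------------------------------------------------
# Fields (HDF5 layout: /grid attrs, /time, /velocity, /mask)
# ---------------------------------------------------------------------------

def _write_grid(f, grid: GridSpec):
    g = f.create_group("grid")
    g.attrs["origin_mm"] = grid.origin
    g.attrs["spacing_mm"] = grid.spacing
    g.attrs["shape"] = grid.shape
    g.attrs["time_step_s"] = grid.time_step
    g.attrs["n_steps"] = grid.n_steps


def _read_grid(f) -> GridSpec:
    g = f["grid"]
    return GridSpec(tuple(g.attrs["origin_mm"]), tuple(g.attrs["spacing_mm"]),
                    tuple(int(x) for x in g.attrs["shape"]),
                    float(g.attrs["time_step_s"]), int(g.attrs["n_steps"]))


def write_flow_h5(flow: FlowField4D, path, seed=None, config_hash=None) -> None:
    with h5py.File(path, "w") as f:
        _stamp(f, cycle_period_s=flow.cycle_period, seed=seed, config_hash=config_hash)
        _write_grid(f, flow.grid)
        f.create_dataset("time", data=flow.grid.times())
        f.create_dataset("velocity", data=flow.velocity, compression="gzip")
        f.create_dataset("mask", data=flow.mask, compression="gzip")


def read_flow_h5(path) -> FlowField4D:
    with h5py.File(path, "r") as f:
        _check_schema(f)
        return FlowField4D(_read_grid(f), f["velocity"][()], f["mask"][()],
                           cycle_period=float(f.attrs.get("cycle_period_s", 0.0)))


def write_pressure_h5(p: PressureField4D, path, seed=None, config_hash=None) -> None:
    with h5py.File(path, "w") as f:
        _stamp(f, reference_note=p.reference_note, seed=seed, config_hash=config_hash)
        _write_grid(f, p.grid)
        f.create_dataset("time", data=p.grid.times())
        f.create_dataset("pressure", data=p.pressure, compression="gzip")
        f.create_dataset("pressure_mmHg", data=p.pressure_mmhg(), compression="gzip")
        f.create_dataset("mask", data=p.mask, compression="gzip")


def read_pressure_h5(path) -> PressureField4D:
    with h5py.File(path, "r") as f:
        _check_schema(f)
        return PressureField4D(_read_grid(f), f["pressure"][()], f["mask"][()],
                               reference_note=str(f.attrs.get("reference_note", "")))


# ---------------------------------------------------------------------------
# Legacy-VTK ASCII structured points (visualisation export)
# ---------------------------------------------------------------------------

def write_flow_vtk(flow: FlowField4D, path_pattern, scalars: dict | None = None) -> list:
    """One legacy-VTK ASCII file per time step (fields: velocity, mask,
    plus optional named scalar arrays such as lambda2 or pressure_mmHg).

    ``path_pattern`` must contain ``{step}``; returns the written paths.
    """
    paths = []
    g = flow.grid
    npts = g.n_voxels
    for t in range(flow.n_steps):
        path = Path(str(path_pattern).format(step=t))
        with open(path, "w") as fh:
            fh.write("# vtk DataFile Version 3.0\n")
            fh.write(f"lv4dflow t={t * g.time_step:.6f}s; units mm, m/s; {_CONVENTION}\n")
            fh.write("ASCII\nDATASET STRUCTURED_POINTS\n")
            fh.write(f"DIMENSIONS {g.shape[0]} {g.shape[1]} {g.shape[2]}\n")
            fh.write(f"ORIGIN {g.origin[0] + g.spacing[0] / 2} "
                     f"{g.origin[1] + g.spacing[1] / 2} {g.origin[2] + g.spacing[2] / 2}\n")
            fh.write(f"SPACING {g.spacing[0]} {g.spacing[1]} {g.spacing[2]}\n")
            fh.write(f"POINT_DATA {npts}\n")
            fh.write("VECTORS velocity float\n")
            v3 = flow.velocity[t].transpose(2, 1, 0, 3).reshape(-1, 3).astype(np.float32)
            np.savetxt(fh, v3, fmt="%.7g")
            fh.write("SCALARS mask int 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, flow.mask[t].transpose(2, 1, 0).reshape(-1, 1), fmt="%d")
            for name, arr in (scalars or {}).items():
                fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                np.savetxt(fh, arr[t].transpose(2, 1, 0).reshape(-1, 1).astype(np.float32),
                           fmt="%.7g")
        paths.append(path)
    return paths


def read_vtk_structured_points(path) -> dict:
    """Minimal reader for the files written by :func:`write_flow_vtk`."""
    out: dict = {"fields": {}}
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    dims = None
    while i < len(lines):
        tok = lines[i].split()
        if not tok:
            i += 1
            continue
        key = tok[0].upper()
        if key == "DIMENSIONS":
            dims = tuple(int(x) for x in tok[1:4])
        elif key == "ORIGIN":
            out["origin_center_mm"] = tuple(float(x) for x in tok[1:4])
        elif key == "SPACING":
            out["spacing_mm"] = tuple(float(x) for x in tok[1:4])
        elif key == "VECTORS":
            n = dims[0] * dims[1] * dims[2]
            vals = np.loadtxt(lines[i + 1:i + 1 + n])
            out["fields"][tok[1]] = vals.reshape(dims[2], dims[1], dims[0], 3
                                                 ).transpose(2, 1, 0, 3)
            i += n
        elif key == "SCALARS":
            n = dims[0] * dims[1] * dims[2]
            vals = np.loadtxt(lines[i + 2:i + 2 + n])
            out["fields"][tok[1]] = vals.reshape(dims[2], dims[1], dims[0]
                                                 ).transpose(2, 1, 0)
            i += n + 1
        i += 1
    out["dimensions"] = dims
    return out


# ---------------------------------------------------------------------------
# Images
# ---------------------------------------------------------------------------

def write_image_sequence(images: ImageSequence, cam: CameraModel, out_dir,
                         seed=None) -> dict:
    """Multi-page TIFF per view plus a JSON metadata sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for v in range(images.n_views):
        p = out_dir / f"view{v}.tif"
        tifffile.imwrite(p, images.frames[:, v], photometric="minisblack")
        paths.append(str(p))
    meta = {
        "schema_version": SCHEMA_VERSION,
        "frame_rate_hz": images.frame_rate,
        "n_views": images.n_views,
        "image_shape": list(images.image_shape),
        "camera": {
            "rotations": cam.rotations.tolist(),
            "mm_per_px": cam.mm_per_px,
            "origin_mm": cam.origin_mm.tolist(),
            "center_px": np.asarray(cam.center_px).tolist(),
            "otf_sigma_px": cam.otf_sigma,
            "peak_intensity": cam.peak_intensity,
        },
        "seed": seed,
        "views": paths,
    }
    with open(out_dir / "images.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    return meta


def read_image_sequence(out_dir) -> tuple[ImageSequence, CameraModel]:
    out_dir = Path(out_dir)
    with open(out_dir / "images.json") as fh:
        meta = json.load(fh)
    if meta.get("schema_version") != SCHEMA_VERSION:
        raise SchemaError(f"unknown image schema version {meta.get('schema_version')!r}")
    frames = np.stack([tifffile.imread(out_dir / f"view{v}.tif")
                       for v in range(meta["n_views"])], axis=1)
    c = meta["camera"]
    cam = CameraModel(np.asarray(c["rotations"]), c["mm_per_px"],
                      tuple(meta["image_shape"]), np.asarray(c["origin_mm"]),
                      np.asarray(c["center_px"]), c["otf_sigma_px"], c["peak_intensity"])
    return ImageSequence(frames, meta["frame_rate_hz"], metadata=meta), cam


# ---------------------------------------------------------------------------
# POD results
# ---------------------------------------------------------------------------

def write_pod_h5(r: PODResult, path, seed=None, config_hash=None) -> None:
    with h5py.File(path, "w") as f:
        _stamp(f, seed=seed, config_hash=config_hash,
               subtract_mean=r.subtract_mean, n_truncated=r.n_truncated)
        _write_grid(f, r.reference_grid)
        f.create_dataset("modes", data=r.modes, compression="gzip")
        f.create_dataset("coefficients", data=r.coefficients)
        f.create_dataset("eigenvalues", data=r.eigenvalues)
        f.create_dataset("reference_mask", data=r.reference_mask, compression="gzip")
        f.create_dataset("snapshot_times", data=r.snapshot_times)
        m = f.create_group("meta")
        m.attrs["energy_fractions"] = r.energy_fractions()
    sidecar = Path(str(path)).with_suffix(".fractions.json")
    with open(sidecar, "w") as fh:
        json.dump({"energy_fractions": r.energy_fractions().tolist(),
                   "cumulative_fractions": r.cumulative_fractions().tolist()}, fh, indent=1)


def read_pod_h5(path) -> PODResult:
    with h5py.File(path, "r") as f:
        _check_schema(f)
        return PODResult(f["modes"][()], f["coefficients"][()], f["eigenvalues"][()],
                         _read_grid(f), f["reference_mask"][()],
                         f["snapshot_times"][()],
                         n_truncated=int(f.attrs.get("n_truncated", 0)),
                         subtract_mean=bool(f.attrs.get("subtract_mean", False)))
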