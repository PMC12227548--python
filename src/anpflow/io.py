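"""Readers and writers for the pipeline's on-disk formats.

Velocity fields and tracks travel as CSV (``t,x,y,u,v,mask`` and
``id,t,x,y,z``), singularity configurations as versioned JSON, image
volumes and plane stacks as TIFF, and surface maps as a flat ``.npz``
container with a JSON header.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .fields import GridSpec, Track, TrackSet, VelocityField
from .projection import PlaneStack, SurfaceMap
from .singularities import SingularityConfig

__all__ = ["write_field_csv", "read_field_csv", "write_tracks_csv",
           "read_tracks_csv", "write_volume_tiff", "read_volume_tiff",
           "write_plane_stack", "read_plane_stack", "write_surface_map",
           "read_surface_map"]


# -- velocity fields -------------------------------------------------------

def write_field_csv(field: VelocityField, path: str | Path) -> None:
    X, Y = field.grid.meshgrid()
    df = pd.DataFrame({
        "t": np.full(X.size, field.time),
        "x": X.ravel(), "y": Y.ravel(),
        "u": field.u.ravel(), "v": field.v.ravel(),
        "mask": field.mask.ravel().astype(int),
    })
    df.to_csv(path, index=False)


def read_field_csv(path: str | Path) -> list[VelocityField]:
    """Read one field per distinct timestamp, sorted by time."""
    df = pd.read_csv(path)
    out = []
    for t, sub in df.groupby("t", sort=True, dropna=False):
        x = np.unique(sub["x"].to_numpy())
        y = np.unique(sub["y"].to_numpy())
        grid = GridSpec(x, y)
        piv = sub.pivot_table(index="y", columns="x", sort=True)
        u = piv["u"].to_numpy()
        v = piv["v"].to_numpy()
        if "mask" in sub.columns:
            mask = piv["mask"].to_numpy() > 0.5
        else:
            mask = np.isfinite(u) & np.isfinite(v)
        u = np.where(mask, u, 0.0)
        v = np.where(mask, v, 0.0)
        out.append(VelocityField(grid, u, v, mask,
                                 time=float(t) if np.isfinite(t) else
                                 float("nan")))
    return out


# -- tracks ----------------------------------------------------------------

def write_tracks_csv(tracks: TrackSet, path: str | Path) -> None:
    rows = []
    for tr in tracks:
        for i in range(tr.t.size):
            rows.append((tr.track_id, tr.t[i], tr.x[i], tr.y[i], tr.z[i]))
    pd.DataFrame(rows, columns=["id", "t", "x", "y", "z"]).to_csv(
        path, index=False)


def read_tracks_csv(path: str | Path) -> TrackSet:
    df = pd.read_csv(path)
    tracks = []
    for tid, sub in df.groupby("id", sort=True):
        sub = sub.sort_values("t")
        tracks.append(Track(int(tid), sub["t"].to_numpy(),
                            sub["x"].to_numpy(), sub["y"].to_numpy(),
                            sub["z"].to_numpy()))
    return TrackSet(tracks)


# -- volumes and plane stacks ---------------------------------------------

def write_volume_tiff(volume, directory: str | Path, stem: str,
                      timepoint: int = 0) -> list[Path]:
    """One multi-page TIFF per channel: ``{stem}_t{TTT}_c{channel}.tif``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, arr in volume.channels.items():
        p = directory / f"{stem}_t{timepoint:03d}_c{name}.tif"
        tifffile.imwrite(p, np.asarray(arr, dtype=np.float32),
                         photometric="minisblack",
                         metadata={"voxel_size": list(volume.voxel_size),
                                   "time_hpf": volume.time})
        paths.append(p)
    return paths


def read_volume_tiff(directory: str | Path, stem: str, timepoint: int = 0,
                     voxel_size=(1.0, 1.0, 1.0)):
    from .synthetic import EmbryoVolume
    directory = Path(directory)
    pattern = f"{stem}_t{timepoint:03d}_c*.tif"
    channels = {}
    for p in sorted(directory.glob(pattern)):
        name = p.stem.split("_c", 1)[1]
        channels[name] = tifffile.imread(p)
    if not channels:
        raise FileNotFoundError(f"no volumes matching {pattern}")
    return EmbryoVolume(channels, tuple(voxel_size))


def write_plane_stack(stack: PlaneStack, path: str | Path) -> None:
    tifffile.imwrite(path, stack.layers.astype(np.float32),
                     photometric="minisblack",
                     metadata={"depth_step": stack.depth_step,
                               "provenance": stack.provenance})


def read_plane_stack(path: str | Path, depth_step: float = 1.0
                     ) -> PlaneStack:
    arr = tifffile.imread(path).astype(float)
    if arr.ndim == 2:
        arr = arr[None]
    return PlaneStack(arr, depth_step, np.isfinite(arr))


# -- surface maps ----------------------------------------------------------

def write_surface_map(smap: SurfaceMap, path: str | Path) -> None:
    """Flat binary (.npz) plus an embedded JSON header."""
    header = json.dumps({
        "rotation_z": smap.rotation_z,
        "origin_um": smap.origin_um.tolist(),
        "orientation": smap.orientation,
        "voxel_size": list(smap.voxel_size),
    })
    np.savez_compressed(path, grid_x=smap.grid_x, grid_y=smap.grid_y,
                        height=smap.height, surface_xyz=smap.surface_xyz,
                        normals=smap.normals, valid=smap.valid,
                        header=np.frombuffer(header.encode(),
                                             dtype=np.uint8))


def read_surface_map(path: str | Path) -> SurfaceMap:
    with np.load(path) as z:
        header = json.loads(bytes(z["header"]).decode())
        return SurfaceMap(z["grid_x"], z["grid_y"], z["height"],
                          z["surface_xyz"], z["normals"],
                          z["valid"].astype(bool),
                          float(header["rotation_z"]),
                          np.asarray(header["origin_um"]),
                          header["orientation"],
                          tuple(header["voxel_size"]))
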