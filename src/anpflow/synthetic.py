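"""Synthetic inputs with known ground truth for every pipeline stage.

* :func:`make_phantom_embryo` — a spherical-cap embryo phantom: a membrane
  channel with bright ridges at Voronoi-cell boundaries on a shell of
  known radius, and a tissue-marker channel whose anterior boundary is a
  straight front at a known angle.  The accompanying
  :class:`PhantomTruth` records the exact geometry, so surface projection
  and segmentation can be scored against analytic truth.
* :func:`make_flow_field` — a velocity field evaluated from a known
  :class:`SingularityConfig` plus i.i.d. Gaussian noise scaled to the RMS
  speed.
* :func:`advect_particles` — RK2 (midpoint) trajectories through a field
  sequence, emulating tracked cells.
* :func:`make_image_pair` — a textured image and its warp by a known
  displacement field, the test input for the PIV surrogate.

All randomness comes from one seeded generator per call; identical
arguments and seed give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .brinkman import evaluate_model
from .fields import GridSpec, Track, TrackSet, VelocityField
from .singularities import SingularityConfig

__all__ = ["EmbryoVolume", "PhantomTruth", "FlowTruth",
           "make_phantom_embryo", "make_flow_field", "advect_particles",
           "make_image_pair"]


@dataclass
class EmbryoVolume:
    """Multi-channel 3D voxel grid with physical spacings.

    Arrays are indexed ``[z, y, x]``; ``voxel_size`` is (dx, dy, dz) µm.
    """

    channels: dict[str, np.ndarray]
    voxel_size: tuple[float, float, float]
    time: float = float("nan")  # hpf

    def __post_init__(self):
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError("all channels must share one shape")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be strictly positive")
        for name, c in self.channels.items():
            if not np.all(np.isfinite(c)) or np.any(c < 0):
                raise ValueError(f"channel {name!r} must be finite and "
                                 "non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class PhantomTruth:
    """Exact geometry of a generated phantom."""

    sphere_center: np.ndarray        # µm, (x, y, z)
    sphere_radius: float             # µm
    cap_half_angle: float            # rad
    shell_thickness: float           # µm
    cell_labels: np.ndarray          # 3D int array, 0 = background
    front_line: np.ndarray           # (n, 2) polyline, in-plane µm coords
    rotation_applied: float          # rad
    marker_mask: np.ndarray | None = None

    def __post_init__(self):
        if self.front_line.shape[0] < 2:
            raise ValueError("front_line must have >= 2 vertices")


@dataclass(frozen=True)
class FlowTruth:
    config: SingularityConfig
    noise_sigma: float
    seed: int

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


# --------------------------------------------------------------------------
# phantom embryo
# --------------------------------------------------------------------------

def make_phantom_embryo(radius: float = 100.0,
                        cap_half_angle: float = np.pi / 3,
                        n_cells: int = 220,
                        voxel_size: tuple[float, float, float] = (1, 1, 1),
                        marker_fraction: float = 0.45,
                        seed: int = 0,
                        shell_thickness: float = 12.0,
                        rotation: float = 0.0,
                        noise_level: float = 0.05,
                        ) -> tuple[EmbryoVolume, PhantomTruth]:
    """Generate a spherical-cap embryo phantom with known geometry.

    The outer surface is a sphere cap of ``radius`` (µm) facing +z; the
    cellular shell extends ``shell_thickness`` below it.  The membrane
    channel carries Gaussian-blurred bright ridges at the boundaries of a
    Voronoi tessellation of ``n_cells`` seeded on the cap, plus additive
    noise.  The marker channel covers the shell on one side of a vertical
    plane whose in-plane normal is at ``rotation`` from +y, so that its
    boundary — the tissue front — projects to a straight line at the known
    angle ``rotation`` from the x-axis.
    """
    voxel_size = tuple(float(v) for v in voxel_size)
    if radius < 10 * max(voxel_size):
        raise ValueError("radius must be >= 10 * max(voxel_size)")
    if n_cells < 4:
        raise ValueError("n_cells must be >= 4")
    cap_area = 2 * np.pi * radius ** 2 * (1 - np.cos(cap_half_angle))
    if cap_area < n_cells * (2 * max(voxel_size)) ** 2:
        raise ValueError(
            f"cap too small to contain {n_cells} cells: area "
            f"{cap_area:.0f} µm² < {n_cells} x minimum cell footprint")
    rng = np.random.default_rng(seed)

    dx, dy, dz = voxel_size
    margin = 6.0
    half_xy = radius * np.sin(cap_half_angle) + margin
    depth = radius * (1 - np.cos(cap_half_angle)) + shell_thickness + margin
    nx = int(np.ceil(2 * half_xy / dx))
    ny = int(np.ceil(2 * half_xy / dy))
    nz = int(np.ceil(depth / dz)) + 1
    # sphere centre below the stack so the cap apex is near the top
    cx, cy = nx * dx / 2.0, ny * dy / 2.0
    cz = (nz - 1) * dz - margin - radius
    center = np.array([cx, cy, cz])

    zs = np.arange(nz) * dz
    ys = np.arange(ny) * dy
    xs = np.arange(nx) * dx
    Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")
    R = np.sqrt((X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        polar = np.arccos(np.clip((Z - cz) / np.where(R > 0, R, 1), -1, 1))
    shell = (R <= radius) & (R >= radius - shell_thickness) & \
        (polar <= cap_half_angle)

    # Voronoi seeds on the cap (uniform in area), as unit directions
    cos_t = rng.uniform(np.cos(cap_half_angle), 1.0, n_cells)
    sin_t = np.sqrt(1 - cos_t ** 2)
    phi = rng.uniform(0, 2 * np.pi, n_cells)
    seeds = np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi),
                             cos_t])

    pts = np.column_stack([(X[shell] - cx), (Y[shell] - cy),
                           (Z[shell] - cz)])
    dirs = pts / np.linalg.norm(pts, axis=1, keepdims=True)
    tree = cKDTree(seeds)
    dists, idx = tree.query(dirs, k=2)
    # chordal -> arc-length scale: ridge where 1st and 2nd seed equidistant
    ridge_sep = (dists[:, 1] - dists[:, 0]) * radius
    ridge_val = np.exp(-0.5 * (ridge_sep / 1.5) ** 2)

    labels = np.zeros((nz, ny, nx), dtype=np.int32)
    labels[shell] = idx[:, 0] + 1

    membrane = np.zeros((nz, ny, nx), dtype=np.float32)
    membrane[shell] = 0.25 + 0.75 * ridge_val
    membrane = ndimage.gaussian_filter(membrane, sigma=1.0)
    membrane += noise_level * rng.standard_normal(membrane.shape)
    membrane = np.clip(membrane, 0, None).astype(np.float32)

    # marker region: one side of a vertical plane; the front line lies at
    # ``rotation`` from +x and the marker occupies the −y side (for
    # rotation = 0), so the away-from-marker axis points to +y
    n_hat = np.array([np.sin(rotation), -np.cos(rotation)])
    marker = np.zeros((nz, ny, nx), dtype=np.float32)
    front_pts = np.empty((0, 2))
    marker_mask = np.zeros((nz, ny, nx), dtype=bool)
    if marker_fraction > 0:
        proj = (X[shell] - cx) * n_hat[0] + (Y[shell] - cy) * n_hat[1]
        cut = np.quantile(proj, 1 - marker_fraction)
        sel = proj >= cut
        marker_mask[shell] = sel
        marker[marker_mask] = 1.0
        marker = ndimage.gaussian_filter(marker, sigma=1.0)
        marker += noise_level * rng.standard_normal(marker.shape)
        marker = np.clip(marker, 0, None).astype(np.float32)
        # front polyline: the cut line in the (x, y) plane, clipped to the
        # cap's in-plane extent
        t_hat = np.array([np.cos(rotation), np.sin(rotation)])
        half = radius * np.sin(cap_half_angle)
        ts = np.linspace(-half, half, 33)
        front_pts = (np.array([cx, cy]) + cut * n_hat
                     + ts[:, None] * t_hat)
    else:
        front_pts = np.array([[cx, cy], [cx + 1.0, cy]])

    vol = EmbryoVolume({"membrane": membrane, "marker": marker},
                       voxel_size)
    truth = PhantomTruth(center, float(radius), float(cap_half_angle),
                         float(shell_thickness), labels, front_pts,
                         float(rotation), marker_mask)
    return vol, truth


# --------------------------------------------------------------------------
# flow fields, tracks, image pairs
# --------------------------------------------------------------------------

def make_flow_field(config: SingularityConfig, grid: GridSpec,
                    noise_sigma: float = 0.0, seed: int = 0,
                    time: float = float("nan")
                    ) -> tuple[VelocityField, FlowTruth]:
    """Model flow on a grid plus Gaussian noise scaled to the RMS speed."""
    fld = evaluate_model(config, grid, time=time)
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        s = noise_sigma * fld.rms_speed()
        fld.u = fld.u + s * rng.standard_normal(fld.u.shape)
        fld.v = fld.v + s * rng.standard_normal(fld.v.shape)
    return fld, FlowTruth(config, float(noise_sigma), int(seed))


def _interp_field(fld: VelocityField, pts: np.ndarray) -> np.ndarray:
    """Bilinear velocity lookup at (n, 2) points; NaN outside the grid."""
    from scipy.interpolate import RegularGridInterpolator
    gi_u = RegularGridInterpolator((fld.y, fld.x), fld.u, bounds_error=False)
    gi_v = RegularGridInterpolator((fld.y, fld.x), fld.v, bounds_error=False)
    q = pts[:, ::-1]  # (y, x) order
    return np.column_stack([gi_u(q), gi_v(q)])


def advect_particles(fields: list[VelocityField], starts: np.ndarray,
                     dt: float, method: str = "rk2") -> TrackSet:
    """Advect particles through a field sequence (µm, min).

    RK2 midpoint by default (Euler available for tests); each step holds
    the field of the current frame.  Particles leaving the grid are
    truncated and flagged.
    """
    if not fields:
        raise ValueError("empty field sequence")
    if method not in ("rk2", "euler"):
        raise ValueError(f"unknown integrator {method!r}")
    starts = np.atleast_2d(np.asarray(starts, dtype=float))
    n = starts.shape[0]
    pos = starts.copy()
    alive = np.ones(n, dtype=bool)
    history = [pos.copy()]
    for fld in fields[:-1]:
        uv = _interp_field(fld, pos)
        if method == "rk2":
            mid = pos + 0.5 * dt * uv
            uv_mid = _interp_field(fld, mid)
            uv = np.where(np.isfinite(uv_mid), uv_mid, uv)
        bad = ~np.isfinite(uv).all(axis=1)
        uv[bad] = 0.0
        alive &= ~bad
        step = np.where(alive[:, None], dt * uv, 0.0)
        pos = pos + step
        history.append(pos.copy())
    arr = np.stack(history)  # (n_frames, n_particles, 2)
    t = np.array([i * dt for i in range(len(fields))])
    tracks = []
    for i in range(n):
        tracks.append(Track(i, t, arr[:, i, 0], arr[:, i, 1],
                            truncated=not alive[i]))
    return TrackSet(tracks)


def make_image_pair(displacement: VelocityField, texture_seed: int = 0,
                    texture_sigma: float = 1.0,
                    shape: tuple[int, int] | None = None
                    ) -> tuple[np.ndarray, np.ndarray]:
    """A textured image and its subpixel warp by a displacement field.

    ``displacement.u/v`` are displacements in pixels between the frames;
    the second image is the first backward-warped so that features move by
    (+u, +v).  Displacements must stay below half a PIV interrogation
    window for recovery to be well-posed.
    """
    if shape is None:
        shape = (int(displacement.y[-1]) + 1, int(displacement.x[-1]) + 1)
    rng = np.random.default_rng(texture_seed)
    img = ndimage.gaussian_filter(rng.random(shape), texture_sigma)
    img = (img - img.min()) / max(np.ptp(img), 1e-12)

    yy, xx = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
    from scipy.interpolate import RegularGridInterpolator
    gi_u = RegularGridInterpolator((displacement.y, displacement.x),
                                   displacement.u, bounds_error=False,
                                   fill_value=0.0)
    gi_v = RegularGridInterpolator((displacement.y, displacement.x),
                                   displacement.v, bounds_error=False,
                                   fill_value=0.0)
    pts = np.column_stack([yy.ravel(), xx.ravel()])
    du = gi_u(pts).reshape(shape)
    dv = gi_v(pts).reshape(shape)
    warped = ndimage.map_coordinates(img, [yy - dv, xx - du], order=1,
                                     mode="nearest")
    return img, warped
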