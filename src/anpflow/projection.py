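"""Curved-surface projection of embryo volumes into aligned planar layers.

The curved outer surface of the embryo is mapped to a plane in a
length-preserving way: after translating the origin (a point on the tissue
front) to (0,0,0), each surface point ``p = (x, y, z)`` maps to
``q = r(p)·(x, y)`` with the scale factor ``r(p)`` chosen so that ``|q| =
|p|``.  Distances from the origin along the surface chord are therefore
preserved exactly; on a sphere of radius R a point at polar angle φ from
the origin lands at planar radius 2R·sin(φ/2).  Deeper layers are sampled
by translating surface points along the inward surface normal in steps of
the original z-resolution, yielding a stack of planar images to which
standard 2D image analysis applies.

Alignment of the planar frame uses the tissue-marker channel: the front of
the marker region is detected from the boundary contour of its thresholded
z-projection via the modal direction of medium-length chords, and the
frame is rotated so the front lies along the x-axis with +y pointing away
from the marker region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.interpolate import griddata
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from skimage.filters import threshold_otsu
from skimage.measure import find_contours, label as sk_label

__all__ = ["AlignmentError", "SegmentationError", "AlignedFrame",
           "SurfaceMap", "PlaneStack", "align_frame", "segment_embryo",
           "extract_surface", "build_projection", "project_volume",
           "unproject_points"]


class AlignmentError(RuntimeError):
    """Front detection / frame alignment failed; message names the step."""


class SegmentationError(RuntimeError):
    """Embryo segmentation produced no foreground."""


@dataclass
class AlignedFrame:
    """In-plane rotation and origin aligning the front with the x-axis."""

    rotation_z: float              # rad; angle of the front from +x
    origin: np.ndarray             # (x, y) voxel coordinates
    front_points: np.ndarray       # (n, 2) ordered (x, y) points
    axis_u: np.ndarray             # unit vector away from the marker region
    axis_v: np.ndarray             # unit vector along the front

    def __post_init__(self):
        if abs(float(self.axis_u @ self.axis_v)) > 1e-9:
            raise ValueError("axes must be orthonormal")


# --------------------------------------------------------------------------
# frame alignment
# --------------------------------------------------------------------------

def align_frame(marker_channel: np.ndarray,
                internalisation_timepoint: int | None = None,
                chord_range: tuple[float, float] = (20.0, 200.0),
                bin_width: float = np.pi / 10,
                max_contour_points: int = 600) -> AlignedFrame:
    """Detect the marker-region front and the aligned planar frame.

    Mean-intensity z-projection → Otsu threshold → largest connected
    component → boundary contour; chords of length 20–200 px between
    contour points are binned by unsigned direction (bin width π/10);
    chords in the modal and adjacent bins define connectivity, and the
    largest connected point set is the front.  The new x-direction is the
    average signed chord direction along the sorted front; the new
    y-direction is perpendicular, pointing away from the marker region.
    """
    arr = np.asarray(marker_channel, dtype=float)
    if arr.ndim == 4:
        if internalisation_timepoint is None:
            raise ValueError("4D input needs internalisation_timepoint")
        arr = arr[internalisation_timepoint]
    if arr.ndim != 3:
        raise ValueError("marker channel must be 3D (z, y, x)")
    zproj = arr.mean(axis=0)
    if not np.any(zproj > 0) or np.ptp(zproj) == 0:
        raise AlignmentError("otsu threshold: marker channel is empty")
    thr = threshold_otsu(zproj)
    binary = zproj > thr
    if not binary.any():
        raise AlignmentError("otsu threshold: no foreground")
    lab = sk_label(binary)
    largest = np.argmax(np.bincount(lab.ravel())[1:]) + 1
    region = lab == largest

    contours = find_contours(region.astype(float), 0.5)
    contour = max(contours, key=len)          # (row, col) = (y, x)
    pts = contour[:, ::-1]                    # -> (x, y)
    if len(pts) > max_contour_points:
        step = len(pts) / max_contour_points
        pts = pts[np.round(np.arange(max_contour_points) * step).astype(int)]
    n = len(pts)

    diff = pts[None, :, :] - pts[:, None, :]
    length = np.hypot(diff[..., 0], diff[..., 1])
    iu, ju = np.triu_indices(n, k=1)
    ok = (length[iu, ju] >= chord_range[0]) & \
         (length[iu, ju] <= chord_range[1])
    if not ok.any():
        raise AlignmentError("chord selection: no chords of length "
                             f"{chord_range[0]}-{chord_range[1]} px")
    ci, cj = iu[ok], ju[ok]
    ang = np.arctan2(diff[ci, cj, 1], diff[ci, cj, 0]) % np.pi
    nbins = int(round(np.pi / bin_width))
    which = np.minimum((ang / bin_width).astype(int), nbins - 1)
    counts = np.bincount(which, minlength=nbins)
    modal = int(np.argmax(counts))
    keep_bins = {(modal - 1) % nbins, modal, (modal + 1) % nbins}
    keep = np.isin(which, list(keep_bins))
    ci, cj = ci[keep], cj[keep]

    graph = coo_matrix((np.ones(ci.size), (ci, cj)), shape=(n, n))
    n_comp, comp = connected_components(graph, directed=False)
    in_graph = np.zeros(n, dtype=bool)
    in_graph[ci] = True
    in_graph[cj] = True
    sizes = np.bincount(comp[in_graph], minlength=n_comp)
    front_idx = np.nonzero((comp == np.argmax(sizes)) & in_graph)[0]
    if front_idx.size < 3:
        raise AlignmentError("front detection: fewer than 3 front points")
    front_idx.sort()                          # position along the contour
    front = pts[front_idx]

    # average signed chord direction along the sorted front; restricted to
    # modal-bin chords — adjacent-bin chords hug the curved region rim and
    # bias the front direction on strongly curved outlines
    on_front = np.isin(ci, front_idx) & np.isin(cj, front_idx)
    fi, fj = ci[on_front], cj[on_front]
    vecs = pts[np.maximum(fi, fj)] - pts[np.minimum(fi, fj)]
    f_ang = np.arctan2(vecs[:, 1], vecs[:, 0]) % np.pi
    in_modal = np.minimum((f_ang / bin_width).astype(int), nbins - 1) == modal
    v = vecs[in_modal].mean(axis=0) if in_modal.any() else vecs.mean(axis=0)
    v = v / np.linalg.norm(v)

    ys, xs = np.nonzero(region)
    weights = zproj[ys, xs]
    marker_com = np.array([np.average(xs, weights=weights),
                           np.average(ys, weights=weights)])
    away = front.mean(axis=0) - marker_com
    u = away - (away @ v) * v
    nu = np.linalg.norm(u)
    if nu < 1e-9:
        raise AlignmentError("axis construction: front passes through the "
                             "marker centre of mass")
    u = u / nu
    # start of the sorted front chosen to preserve axis handedness
    if v[0] * u[1] - v[1] * u[0] < 0:
        v = -v
        front = front[::-1]

    origin = (marker_com @ v) * v + (front.mean(axis=0) @ u) * u
    rot = float(np.arctan2(v[1], v[0]))
    return AlignedFrame(rot, origin, front, u, v)


# --------------------------------------------------------------------------
# embryo segmentation and surface extraction
# --------------------------------------------------------------------------

def _phansalkar(img: np.ndarray, radius: int, k: float = 0.25,
                r: float = 0.5, p: float = 2.0, q: float = 10.0
                ) -> np.ndarray:
    """Phansalkar adaptive threshold on an image normalized to [0, 1]."""
    size = 2 * radius + 1
    mean = ndimage.uniform_filter(img, size=size)
    sq = ndimage.uniform_filter(img * img, size=size)
    std = np.sqrt(np.clip(sq - mean * mean, 0, None))
    thresh = mean * (1 + p * np.exp(-q * mean) + k * (std / r - 1))
    return img > thresh


def segment_embryo(membrane_channel: np.ndarray, smooth_sigma: float = 3.0,
                   phansalkar_radius: int = 30) -> np.ndarray:
    """Whole-embryo binary mask from the membrane channel.

    Gaussian smoothing (s = 3 px) → Phansalkar adaptive threshold
    (radius 30 voxels) → largest connected component.
    """
    arr = np.asarray(membrane_channel, dtype=float)
    lo, hi = arr.min(), arr.max()
    if hi <= lo:
        raise SegmentationError("constant image: no foreground")
    arr = (arr - lo) / (hi - lo)
    arr = ndimage.gaussian_filter(arr, smooth_sigma)
    binary = _phansalkar(arr, phansalkar_radius)
    if not binary.any():
        raise SegmentationError("adaptive threshold found no foreground")
    lab, n = ndimage.label(binary)
    if n == 0:
        raise SegmentationError("no connected component")
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, range(1, n + 1))
    return lab == (int(np.argmax(sizes)) + 1)


def extract_surface(mask: np.ndarray, origin_xy: np.ndarray
                    ) -> tuple[np.ndarray, str]:
    """Outer-surface points of the segmented embryo.

    The half of the z-stack containing the outer surface is auto-detected:
    per z-slice, the mean in-plane distance of mask voxels to the origin
    is computed, and the half with the smaller median (the narrower
    portion of the embryo) holds the outer surface.  The surface is the
    per-(x, y) extremal z of the mask in that direction.

    Returns (points, orientation) with points (n, 3) in voxel coordinates
    (x, y, z) and orientation "min_z" or "max_z".
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    zs = np.nonzero(mask.any(axis=(1, 2)))[0]
    if zs.size < 2:
        raise ValueError("mask spans a single z-slice")
    nz = mask.shape[0]
    ox, oy = float(origin_xy[0]), float(origin_xy[1])
    mean_dist = np.full(nz, np.nan)
    for z in range(nz):
        yy, xx = np.nonzero(mask[z])
        if xx.size:
            mean_dist[z] = np.mean(np.hypot(xx - ox, yy - oy))
    half = nz // 2
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med_lo = np.nanmedian(mean_dist[:half])
        med_hi = np.nanmedian(mean_dist[half:])
    if np.isnan(med_lo) and np.isnan(med_hi):
        raise ValueError("mask has no in-plane voxels")
    if np.isnan(med_hi) or med_lo < med_hi:
        orientation = "min_z"
    elif np.isnan(med_lo) or med_hi < med_lo:
        orientation = "max_z"
    else:
        warnings.warn("z-half medians tie; taking min-z as the outer "
                      "surface", stacklevel=2)
        orientation = "min_z"

    covered = mask.any(axis=0)
    zidx = np.arange(nz)[:, None, None]
    if orientation == "max_z":
        zsurf = np.max(np.where(mask, zidx, -1), axis=0).astype(float)
        zsurf[~covered] = np.nan
    else:
        zsurf = np.min(np.where(mask, zidx, nz + 1), axis=0).astype(float)
        zsurf[~covered] = np.nan
    yy, xx = np.nonzero(covered)
    points = np.column_stack([xx, yy, zsurf[yy, xx]])
    return points, orientation


# --------------------------------------------------------------------------
# the surface map
# --------------------------------------------------------------------------

@dataclass
class SurfaceMap:
    """Forward/inverse length-preserving map between surface and plane.

    Planar coordinates are µm in the aligned frame (front along x, origin
    on the front).  ``surface_xyz`` holds, per planar grid pixel, the 3D
    surface point in the aligned µm frame; ``normals`` the outward unit
    surface normal there.
    """

    grid_x: np.ndarray          # 1D planar µm
    grid_y: np.ndarray
    height: np.ndarray          # smoothed z per planar pixel (µm)
    surface_xyz: np.ndarray     # (ny, nx, 3), aligned frame
    normals: np.ndarray         # (ny, nx, 3), unit, outward
    valid: np.ndarray           # (ny, nx) bool
    rotation_z: float
    origin_um: np.ndarray       # (3,), original-frame µm
    orientation: str            # "min_z" | "max_z"
    voxel_size: tuple[float, float, float]

    # -- frame transforms --------------------------------------------------
    def _rot(self):
        c, s = np.cos(self.rotation_z), np.sin(self.rotation_z)
        return np.array([[c, s], [-s, c]])     # rotates by −rotation_z

    def to_aligned(self, points_um: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points_um) - self.origin_um
        out = p.copy()
        out[:, :2] = p[:, :2] @ self._rot().T
        return out

    def to_original(self, points_al: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points_al).copy()
        p[:, :2] = p[:, :2] @ self._rot()
        return p + self.origin_um

    # -- forward -----------------------------------------------------------
    def forward(self, points_um: np.ndarray) -> np.ndarray:
        """Map original-frame 3D µm points to planar µm coordinates.

        |q| = |p| exactly by construction.
        """
        p = self.to_aligned(points_um)
        rho = np.hypot(p[:, 0], p[:, 1])
        norm3 = np.linalg.norm(p, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            scale = np.where(rho > 1e-12, norm3 / np.where(rho > 1e-12,
                                                           rho, 1.0), 0.0)
        return p[:, :2] * scale[:, None]

    # -- inverse -----------------------------------------------------------
    def _interp(self, grid: np.ndarray, q: np.ndarray) -> np.ndarray:
        from scipy.interpolate import RegularGridInterpolator
        gi = RegularGridInterpolator((self.grid_y, self.grid_x), grid,
                                     bounds_error=False)
        return gi(q[:, ::-1])

    def inverse(self, points_2d: np.ndarray, depth: float = 0.0
                ) -> tuple[np.ndarray, np.ndarray]:
        """Planar µm points → original-frame 3D µm points at given depth.

        Returns (points, valid); points are NaN where invalid (outside
        the mapped domain).
        """
        q = np.atleast_2d(np.asarray(points_2d, dtype=float))
        S = np.stack([self._interp(self.surface_xyz[..., i], q)
                      for i in range(3)], axis=1)
        N = np.stack([self._interp(self.normals[..., i], q)
                      for i in range(3)], axis=1)
        nn = np.linalg.norm(N, axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            N = N / np.where(nn > 1e-12, nn, 1.0)
        out = S - depth * N
        ok = np.all(np.isfinite(out), axis=1)
        res = np.full((len(q), 3), np.nan)
        res[ok] = self.to_original(out[ok])
        return res, ok


@dataclass
class PlaneStack:
    """Stack of planar layers at increasing depth below the surface."""

    layers: np.ndarray          # (n_layers, ny, nx); NaN = sentinel
    depth_step: float           # µm, = original z-resolution
    mask: np.ndarray            # (n_layers, ny, nx) bool
    provenance: str = ""

    def __post_init__(self):
        if self.depth_step <= 0:
            raise ValueError("depth_step must be > 0")


def build_projection(surface_points: np.ndarray, aligned: AlignedFrame,
                     voxel_size: tuple[float, float, float] = (1, 1, 1),
                     orientation: str = "max_z",
                     z_smooth_sigma: float = 20.0,
                     grid_spacing: float | None = None) -> SurfaceMap:
    """Build the length-preserving surface map from extracted surface points.

    The z-origin is the surface z nearest the aligned origin in-plane;
    the inverse map interpolates z linearly onto integer planar
    coordinates, Gaussian-smooths the z-values (s = 20 px), and rescales
    the in-plane coordinates per planar ray to preserve lengths as in the
    forward mapping.
    """
    pts = np.asarray(surface_points, dtype=float)
    if not np.all(np.isfinite(pts)):
        raise ValueError("surface contains non-finite points")
    dx, dy, dz = voxel_size
    pts_um = pts * np.array([dx, dy, dz])
    origin_xy_um = np.asarray(aligned.origin, dtype=float) * \
        np.array([dx, dy])

    d2 = np.hypot(pts_um[:, 0] - origin_xy_um[0],
                  pts_um[:, 1] - origin_xy_um[1])
    z0 = pts_um[np.argmin(d2), 2]
    origin_um = np.array([origin_xy_um[0], origin_xy_um[1], z0])

    # aligned frame: translate then rotate in-plane by −rotation_z
    c, s = np.cos(aligned.rotation_z), np.sin(aligned.rotation_z)
    R = np.array([[c, s], [-s, c]])
    p = pts_um - origin_um
    p[:, :2] = p[:, :2] @ R.T

    rho = np.hypot(p[:, 0], p[:, 1])
    norm3 = np.linalg.norm(p, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(rho > 1e-12, norm3 / np.where(rho > 1e-12, rho,
                                                       1.0), 0.0)
    q = p[:, :2] * scale[:, None]

    h = grid_spacing or float(min(dx, dy))
    gx = np.arange(np.floor(q[:, 0].min()), np.ceil(q[:, 0].max()) + h, h)
    gy = np.arange(np.floor(q[:, 1].min()), np.ceil(q[:, 1].max()) + h, h)
    QX, QY = np.meshgrid(gx, gy)
    z_grid = griddata(q, p[:, 2], (QX, QY), method="linear")
    valid = np.isfinite(z_grid)
    if not valid.any():
        raise ValueError("surface interpolation produced no valid pixels")

    # NaN-aware Gaussian smoothing (normalized convolution)
    w = valid.astype(float)
    zf = np.where(valid, z_grid, 0.0)
    num = ndimage.gaussian_filter(zf, z_smooth_sigma)
    den = ndimage.gaussian_filter(w, z_smooth_sigma)
    with np.errstate(invalid="ignore", divide="ignore"):
        z_smooth = np.where(den > 1e-6, num / den, np.nan)
    z_smooth[~valid] = np.nan

    # inverse: rescale (x, y) along each planar ray to preserve |q| = |p|
    rho_q = np.hypot(QX, QY)
    with np.errstate(invalid="ignore"):
        r_in2 = rho_q ** 2 - z_smooth ** 2
    ok = valid & (r_in2 >= 0)
    r_in = np.sqrt(np.clip(r_in2, 0, None))
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(rho_q > 1e-12, r_in / np.where(rho_q > 1e-12, rho_q,
                                                    1.0), 0.0)
    SX = np.where(ok, QX * f, np.nan)
    SY = np.where(ok, QY * f, np.nan)
    SZ = np.where(ok, z_smooth, np.nan)
    surface_xyz = np.stack([SX, SY, SZ], axis=-1)

    # outward normals from the parameterized surface
    gx_step = gx[1] - gx[0]
    gy_step = gy[1] - gy[0]
    dS_dx = np.stack([np.gradient(surface_xyz[..., i], gx_step, axis=1)
                      for i in range(3)], axis=-1)
    dS_dy = np.stack([np.gradient(surface_xyz[..., i], gy_step, axis=0)
                      for i in range(3)], axis=-1)
    normals = np.cross(dS_dx, dS_dy)
    nn = np.linalg.norm(normals, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore"):
        normals = normals / np.where(nn > 1e-12, nn, 1.0)
    # orient outward: toward increasing z for max_z surfaces, else -z
    sign = 1.0 if orientation == "max_z" else -1.0
    flip = normals[..., 2] * sign < 0
    normals[flip] *= -1
    normals[~ok] = np.nan

    return SurfaceMap(gx, gy, z_smooth, surface_xyz, normals, ok,
                      aligned.rotation_z, origin_um, orientation,
                      tuple(float(v) for v in voxel_size))


def project_volume(volume, surface_map: SurfaceMap, n_layers_below: int,
                   channel: str | None = None,
                   interpolation: str = "nearest") -> PlaneStack:
    """Sample the volume on surface-parallel layers.

    Layer k is sampled at ``surface − k·dz·normal`` (dz = original
    z-resolution); intensities use nearest-neighbour interpolation by
    default.  Samples outside the volume become NaN sentinels.
    """
    from .synthetic import EmbryoVolume  # avoid cycle at import time

    if isinstance(volume, EmbryoVolume):
        if channel is None:
            channel = next(iter(volume.channels))
        arr = volume.channels[channel]
        vs = volume.voxel_size
    else:
        arr = np.asarray(volume)
        vs = surface_map.voxel_size
    dx, dy, dz = vs
    order = 0 if interpolation == "nearest" else 1

    ny, nx = surface_map.valid.shape
    layers = np.full((n_layers_below + 1, ny, nx), np.nan, dtype=float)
    S = surface_map.surface_xyz
    N = surface_map.normals
    flat_ok = surface_map.valid.ravel()
    for k in range(n_layers_below + 1):
        P = S - k * dz * N                     # aligned frame
        P2 = P.reshape(-1, 3)
        good = flat_ok & np.all(np.isfinite(P2), axis=1)
        orig = surface_map.to_original(P2[good])
        coords = np.stack([orig[:, 2] / dz, orig[:, 1] / dy,
                           orig[:, 0] / dx])
        vals = ndimage.map_coordinates(arr.astype(float), coords,
                                       order=order, mode="constant",
                                       cval=np.nan)
        lay = np.full(ny * nx, np.nan)
        lay[good] = vals
        layers[k] = lay.reshape(ny, nx)
    mask = np.isfinite(layers)
    return PlaneStack(layers, float(dz), mask,
                      provenance=f"surface_map@{id(surface_map):x}")


def unproject_points(points_2d: np.ndarray, surface_map: SurfaceMap,
                     depth: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Planar points → original 3D coordinates at the given depth (µm).

    Points outside the mapped domain are flagged invalid and returned as
    NaN rows.
    """
    return surface_map.inverse(points_2d, depth=depth)
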