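"""Tissue- and cell-scale shape measurements on projected layers.

Cell orientation is axial data (θ and θ+π are the same orientation), so
domain statistics use doubled-angle circular means.  Orientations are
reported in (−π/2, π/2] measured from the +x (mediolateral) axis in the
planar frame; a circle's orientation is flagged undefined rather than
given an arbitrary value.

The segmentation validation mirrors the experimental protocol: predicted
cells are matched to ground truth by best overlap, a match counts as a
success at intersection-over-union > 0.6, and per-metric correlations and
size-relative differences are reported for the successes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from skimage.filters import threshold_otsu
from skimage.measure import find_contours
from skimage.morphology import h_minima
from skimage.segmentation import watershed

from .fields import Track
from .projection import SurfaceMap, unproject_points

__all__ = ["TissueShape", "CellShapeRecord", "ValidationReport",
           "DomainOrientation", "tissue_shape", "segment_cells_2d",
           "cell_metrics", "domain_orientation", "internalisation_depth",
           "validate_segmentation"]


# --------------------------------------------------------------------------
# tissue shape
# --------------------------------------------------------------------------

@dataclass
class TissueShape:
    area: float                 # µm²
    width_ml: float             # µm, mean over five AP stations
    outline: np.ndarray         # (n, 2) polygon, µm (x, y)
    station_widths: np.ndarray = field(default_factory=lambda: np.empty(0))


def tissue_shape(marker_projection: np.ndarray, pixel_size: float = 1.0,
                 smooth_sigma: float = 1.0,
                 stations: tuple = (0.1, 0.3, 0.5, 0.7, 0.9)
                 ) -> TissueShape:
    """Segment the projected marker region and measure area and ML width.

    The ML width is the mean tissue width at five stations spaced along
    the AP extent of the outline.
    """
    img = np.asarray(marker_projection, dtype=float)
    img = np.where(np.isfinite(img), img, 0.0)
    if not np.any(img > 0) or np.ptp(img) == 0:
        raise ValueError("empty marker projection")
    sm = ndimage.gaussian_filter(img, smooth_sigma)
    binary = sm > threshold_otsu(sm)
    if not binary.any():
        raise ValueError("segmentation found no tissue")
    binary = ndimage.binary_fill_holes(binary)
    lab, n = ndimage.label(binary)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, range(1, n + 1))
    region = lab == (int(np.argmax(sizes)) + 1)

    area = float(region.sum()) * pixel_size ** 2
    rows = np.nonzero(region.any(axis=1))[0]
    y0, y1 = rows[0], rows[-1]
    widths = []
    for frac in stations:
        r = int(round(y0 + frac * (y1 - y0)))
        cols = np.nonzero(region[r])[0]
        if cols.size:
            widths.append((cols[-1] - cols[0] + 1) * pixel_size)
    contour = max(find_contours(region.astype(float), 0.5), key=len)
    outline = contour[:, ::-1] * pixel_size
    return TissueShape(area, float(np.mean(widths)), outline,
                       np.asarray(widths))


# --------------------------------------------------------------------------
# 2D cell segmentation and ellipse metrics
# --------------------------------------------------------------------------

def segment_cells_2d(membrane_layer: np.ndarray, smooth_sigma: float = 3.0,
                     h_rel: float = 0.05) -> np.ndarray:
    """Seeded watershed segmentation of a membrane-labelled layer.

    Gaussian smoothing (s = 3 px) then watershed on intensity, seeded at
    h-minima of the smoothed image (cells are dark interiors between
    bright membrane ridges).  Labels >= 1; an all-flat image yields an
    empty labelling.
    """
    img = np.asarray(membrane_layer, dtype=float)
    finite = np.isfinite(img)
    if not finite.any() or np.ptp(img[finite]) == 0:
        return np.zeros(img.shape, dtype=np.int32)
    fill = np.nanmax(img[finite])
    img = np.where(finite, img, fill)
    sm = ndimage.gaussian_filter(img, smooth_sigma)
    h = h_rel * np.ptp(sm)
    if h <= 0:
        return np.zeros(img.shape, dtype=np.int32)
    minima = h_minima(sm, h)
    markers, n = ndimage.label(minima)
    if n == 0:
        return np.zeros(img.shape, dtype=np.int32)
    labels = watershed(sm, markers)
    labels[~finite] = 0
    return labels.astype(np.int32)


@dataclass
class CellShapeRecord:
    label: int
    centroid: np.ndarray            # (x, y) µm
    area: float                     # µm²
    orientation: float              # rad in (−π/2, π/2]; NaN if undefined
    orientation_defined: bool
    major: float                    # µm, full major-axis length
    minor: float                    # µm
    axis_endpoints_3d: np.ndarray   # (4, 3): major ±, minor ± endpoints
    major_3d: float                 # back-projected axis lengths
    minor_3d: float
    touches_border: bool = False


def _ellipse_from_moments(ys, xs):
    mx, my = xs.mean(), ys.mean()
    dx = xs - mx
    dy = ys - my
    # second central moments (+1/12 pixel-integration correction)
    c20 = dx @ dx / dx.size + 1 / 12
    c02 = dy @ dy / dy.size + 1 / 12
    c11 = dx @ dy / dx.size
    common = np.sqrt((c20 - c02) ** 2 + 4 * c11 ** 2)
    lmax = (c20 + c02 + common) / 2
    lmin = (c20 + c02 - common) / 2
    theta = 0.5 * np.arctan2(2 * c11, c20 - c02)
    if theta <= -np.pi / 2:
        theta += np.pi
    return (mx, my), 4 * np.sqrt(lmax), 4 * np.sqrt(max(lmin, 0)), theta


def cell_metrics(labels: np.ndarray, surface_map: SurfaceMap | None = None,
                 pixel_size: float = 1.0, depth: float = 0.0,
                 planar_origin: tuple[float, float] = (0.0, 0.0),
                 circle_tol: float = 0.02) -> list[CellShapeRecord]:
    """Per-cell ellipse metrics with back-projected axis endpoints.

    Axis endpoints are mapped through the surface projection (identity if
    no map is given) so lengths can be corrected for mapping distortion.
    ``planar_origin`` places pixel (0, 0) of the label image in the
    map's planar coordinates.
    """
    labels = np.asarray(labels)
    records: list[CellShapeRecord] = []
    border = np.zeros_like(labels, dtype=bool)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True
    for lab in np.unique(labels):
        if lab == 0:
            continue
        mask = labels == lab
        ys, xs = np.nonzero(mask)
        (mx, my), major, minor, theta = _ellipse_from_moments(
            ys.astype(float), xs.astype(float))
        aspect = major / max(minor, 1e-12)
        defined = aspect - 1 > circle_tol
        e_major = np.array([np.cos(theta), np.sin(theta)])
        e_minor = np.array([-np.sin(theta), np.cos(theta)])
        c = np.array([mx, my])
        ends_px = np.array([c + 0.5 * major * e_major,
                            c - 0.5 * major * e_major,
                            c + 0.5 * minor * e_minor,
                            c - 0.5 * minor * e_minor])
        ends_um = ends_px * pixel_size + np.asarray(planar_origin)
        if surface_map is not None:
            ends_3d, ok = unproject_points(ends_um, surface_map,
                                           depth=depth)
            if not ok.all():
                ends_3d = np.column_stack([ends_um,
                                           np.zeros(len(ends_um))])
        else:
            ends_3d = np.column_stack([ends_um, np.zeros(len(ends_um))])
        major_3d = float(np.linalg.norm(ends_3d[0] - ends_3d[1]))
        minor_3d = float(np.linalg.norm(ends_3d[2] - ends_3d[3]))
        records.append(CellShapeRecord(
            label=int(lab),
            centroid=c * pixel_size + np.asarray(planar_origin),
            area=float(mask.sum()) * pixel_size ** 2,
            orientation=float(theta) if defined else float("nan"),
            orientation_defined=bool(defined),
            major=float(major) * pixel_size,
            minor=float(minor) * pixel_size,
            axis_endpoints_3d=ends_3d,
            major_3d=major_3d, minor_3d=minor_3d,
            touches_border=bool((mask & border).any())))
    return records


# --------------------------------------------------------------------------
# domain orientation statistics
# --------------------------------------------------------------------------

@dataclass
class DomainOrientation:
    mean_orientation: float       # rad, axial circular mean; NaN undefined
    mean_elongation: float        # mean aspect ratio of contributing cells
    resultant_length: float       # axial circular resultant (0..1)
    defined: bool
    n_cells: int
    histogram: tuple[np.ndarray, np.ndarray]  # counts, bin edges (rad)


def domain_orientation(records_series, center_track,
                       box: float = 30.0, window: float = 20.0,
                       time: float | None = None,
                       n_bins: int = 18) -> DomainOrientation:
    """Mean orientation/elongation of cells in a tracked 30 µm domain.

    ``records_series`` is a list of ``(time_min, [CellShapeRecord])``;
    ``center_track`` maps time to the domain centre (a callable or an
    (n, 3)/(n, 2) array aligned with the series).  Cells with centroid
    inside the box around the centre, within the 20-min window, enter the
    doubled-angle circular mean; antipodal orientation sets (resultant
    length ~0) are flagged undefined.
    """
    if time is None:
        time = records_series[len(records_series) // 2][0]
    thetas = []
    aspects = []
    for i, (t, recs) in enumerate(records_series):
        if abs(t - time) > window / 2:
            continue
        c = (center_track(t) if callable(center_track)
             else np.asarray(center_track[i], dtype=float))
        for r in recs:
            if not r.orientation_defined:
                continue
            if (abs(r.centroid[0] - c[0]) <= box / 2 and
                    abs(r.centroid[1] - c[1]) <= box / 2):
                thetas.append(r.orientation)
                aspects.append(r.major / max(r.minor, 1e-12))
    if not thetas:
        return DomainOrientation(float("nan"), float("nan"), 0.0, False, 0,
                                 (np.zeros(n_bins),
                                  np.linspace(-np.pi / 2, np.pi / 2,
                                              n_bins + 1)))
    th = np.asarray(thetas)
    C = np.mean(np.cos(2 * th))
    S = np.mean(np.sin(2 * th))
    R = float(np.hypot(C, S))
    defined = R > 1e-6
    mean_theta = 0.5 * np.arctan2(S, C) if defined else float("nan")
    counts, edges = np.histogram(th, bins=n_bins,
                                 range=(-np.pi / 2, np.pi / 2))
    return DomainOrientation(float(mean_theta), float(np.mean(aspects)),
                             R, defined, len(th), (counts, edges))


# --------------------------------------------------------------------------
# internalisation depth
# --------------------------------------------------------------------------

def internalisation_depth(track: Track, surface,
                          max_inplane_gap: float = 5.0
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Per-timepoint minimum distance from a 3D track to the surface (µm).

    ``surface`` is a :class:`SurfaceMap` or an (n, 3) array of surface
    points in the same (original, µm) frame as the track.  Samples whose
    in-plane position falls outside the mapped region (nearest surface
    point farther than ``max_inplane_gap`` in-plane) are masked.
    """
    if isinstance(surface, SurfaceMap):
        S = surface.surface_xyz[surface.valid]
        pts = surface.to_original(S.reshape(-1, 3))
    else:
        pts = np.asarray(surface, dtype=float)
    tree = cKDTree(pts)
    q = track.points()
    dist, idx = tree.query(q)
    nearest = pts[idx]
    inplane = np.hypot(q[:, 0] - nearest[:, 0], q[:, 1] - nearest[:, 1])
    valid = inplane <= np.maximum(max_inplane_gap, dist + 1e-9)
    depths = np.where(valid, dist, np.nan)
    return depths, valid


# --------------------------------------------------------------------------
# segmentation validation
# --------------------------------------------------------------------------

@dataclass
class ValidationReport:
    success_rate: float
    metric_correlations: dict
    mean_relative_differences: dict
    mean_angle_difference: float      # degrees, axial
    n_truth: int
    n_matched: int

    def __post_init__(self):
        if not 0 <= self.success_rate <= 1:
            raise ValueError("success_rate must be in [0, 1]")


def _axial_diff_deg(a, b):
    d = np.degrees(a - b)
    return (d + 90.0) % 180.0 - 90.0


def validate_segmentation(predicted: np.ndarray, truth: np.ndarray,
                          iou_threshold: float = 0.6) -> ValidationReport:
    """Score a predicted labelling against ground truth.

    Each truth cell is matched to the predicted label of largest overlap;
    success requires IoU > 0.6.  For the successes, Pearson correlations
    of area/orientation/major-length, size-relative mean differences and
    the mean axial angle difference are reported.
    """
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("label images must share shape")
    t_labels = np.unique(truth)
    t_labels = t_labels[t_labels != 0]
    if t_labels.size == 0:
        raise ValueError("truth labelling is empty")

    matched = []
    successes = 0
    for tl in t_labels:
        tmask = truth == tl
        overlap = predicted[tmask]
        overlap = overlap[overlap != 0]
        if overlap.size == 0:
            continue
        pl = np.bincount(overlap).argmax()
        pmask = predicted == pl
        inter = np.logical_and(tmask, pmask).sum()
        union = np.logical_or(tmask, pmask).sum()
        iou = inter / union
        if iou > iou_threshold:
            successes += 1
            matched.append((tl, pl))

    success_rate = successes / t_labels.size
    corr = {}
    reldiff = {}
    angle_diff = float("nan")
    if matched:
        tm = {r.label: r for r in cell_metrics(truth)}
        pm = {r.label: r for r in cell_metrics(predicted)}
        pairs = [(tm[tl], pm[pl]) for tl, pl in matched
                 if tl in tm and pl in pm]
        t_area = np.array([a.area for a, _ in pairs])
        p_area = np.array([b.area for _, b in pairs])
        t_len = np.array([a.major for a, _ in pairs])
        p_len = np.array([b.major for _, b in pairs])
        both_or = [(a.orientation, b.orientation) for a, b in pairs
                   if a.orientation_defined and b.orientation_defined]

        def _pearson(x, y):
            if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
                return 1.0 if np.allclose(x, y) else float("nan")
            return float(np.corrcoef(x, y)[0, 1])

        corr["area"] = _pearson(t_area, p_area)
        corr["length"] = _pearson(t_len, p_len)
        reldiff["area"] = float(np.mean((p_area - t_area) / t_area))
        reldiff["length"] = float(np.mean((p_len - t_len) / t_len))
        if both_or:
            ta = np.array([a for a, _ in both_or])
            pa = np.array([b for _, b in both_or])
            corr["orientation"] = _pearson(ta, pa)
            angle_diff = float(np.mean(np.abs(_axial_diff_deg(pa, ta))))
    return ValidationReport(success_rate, corr, reldiff, angle_diff,
                            int(t_labels.size), len(matched))
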