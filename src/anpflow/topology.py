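"""Qualitative flow-topology features used as model discriminators.

A velocity field's fixed points (stagnation points) are located by sign
changes of both components followed by Newton refinement on a spline
interpolant, then classified from the local Jacobian:

* ``extension_point`` — saddle (real eigenvalues of opposite sign):
  stretching along one direction, compression along the other;
* ``center_vortex`` — complex eigenvalues with near-zero trace;
* ``sink_node`` / ``source_node`` — attracting / repelling nodes or spirals.

Regime features aggregate these into the discriminators used to compare
candidate force configurations against the symmetrised experimental-like
flow: presence and sense of lateral vortices, an extension point on the
midline, an axis sink, and the orientation of the turning flow posterior
to the sink.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RectBivariateSpline

from .fields import VelocityField

log = logging.getLogger(__name__)

__all__ = ["FixedPoint", "RegimeFeatures", "find_fixed_points",
           "regime_features", "match_regime"]

#: |trace| / |eigenvalue| below which a rotational fixed point counts as a
#: center rather than a spiral; discretised frictional fields make off-axis
#: centers weakly spiral.
CENTER_TRACE_TOL = 0.1


@dataclass(frozen=True)
class FixedPoint:
    position: tuple[float, float]        # µm
    kind: str                            # extension_point | center_vortex |
                                         # sink_node | source_node
    jacobian: np.ndarray                 # 2×2 local velocity gradient
    poincare_index: int                  # −1 saddle, +1 otherwise
    rotation_sense: int | None = None    # ±1 for vortices (sign of curl)


@dataclass(frozen=True)
class RegimeFeatures:
    has_vortex: bool
    vortex_orientation: int | None       # sense of the x > 0 vortex
    has_extension_point_on_axis: bool
    has_axis_sink: bool
    turning_flow_orientation: int | None  # sign of lateral flow posterior
                                          # to the sink; None if no turning

    def as_dict(self) -> dict:
        return {
            "has_vortex": self.has_vortex,
            "vortex_orientation": self.vortex_orientation,
            "has_extension_point_on_axis": self.has_extension_point_on_axis,
            "has_axis_sink": self.has_axis_sink,
            "turning_flow_orientation": self.turning_flow_orientation,
        }


def _classify(J: np.ndarray) -> tuple[str, int, int | None]:
    eig = np.linalg.eigvals(J)
    det = float(np.linalg.det(J))
    tr = float(np.trace(J))
    curl = J[1, 0] - J[0, 1]
    if det < 0:
        return "extension_point", -1, None
    scale = max(abs(eig[0]), abs(eig[1]), 1e-300)
    if np.iscomplexobj(eig) and np.any(np.abs(np.imag(eig)) > 1e-12 * scale):
        if abs(tr) / scale < CENTER_TRACE_TOL:
            return "center_vortex", 1, int(np.sign(curl))
        return ("sink_node" if tr < 0 else "source_node"), 1, \
            int(np.sign(curl))
    return ("sink_node" if tr < 0 else "source_node"), 1, None


def find_fixed_points(field: VelocityField, newton_tol: float = 1e-9,
                      max_iter: int = 60) -> list[FixedPoint]:
    """Locate and classify all stagnation points of a gridded flow."""
    x, y = field.x, field.y
    su = RectBivariateSpline(y, x, field.u)
    sv = RectBivariateSpline(y, x, field.v)
    scale = field.rms_speed()
    if scale == 0:
        return []

    # candidate cells: both components change sign among the 4 corners
    u, v = field.u, field.v
    def sign_change(a):
        c = np.stack([a[:-1, :-1], a[:-1, 1:], a[1:, :-1], a[1:, 1:]])
        return (c.min(axis=0) <= 0) & (c.max(axis=0) >= 0)

    cand = sign_change(u) & sign_change(v)
    dx = float(x[1] - x[0])
    dy = float(y[1] - y[0])
    found: list[FixedPoint] = []
    for iy, ix in zip(*np.nonzero(cand)):
        p = np.array([0.5 * (x[ix] + x[ix + 1]), 0.5 * (y[iy] + y[iy + 1])])
        ok = False
        for _ in range(max_iter):
            U = np.array([su.ev(p[1], p[0]), sv.ev(p[1], p[0])])
            J = np.array([
                [su.ev(p[1], p[0], dy=1), su.ev(p[1], p[0], dx=1)],
                [sv.ev(p[1], p[0], dy=1), sv.ev(p[1], p[0], dx=1)],
            ])
            if abs(np.linalg.det(J)) < 1e-30:
                break
            step = np.linalg.solve(J, U)
            p = p - step
            if not (x[0] <= p[0] <= x[-1] and y[0] <= p[1] <= y[-1]):
                break
            if np.hypot(*U) < newton_tol * scale and \
                    np.hypot(*step) < 1e-6 * max(dx, dy):
                ok = True
                break
        if not ok:
            log.debug("Newton did not converge from cell (%d, %d)", iy, ix)
            continue
        # deduplicate within one grid cell
        if any(np.hypot(p[0] - q.position[0], p[1] - q.position[1])
               < max(dx, dy) for q in found):
            continue
        J = np.array([
            [su.ev(p[1], p[0], dy=1), su.ev(p[1], p[0], dx=1)],
            [sv.ev(p[1], p[0], dy=1), sv.ev(p[1], p[0], dx=1)],
        ])
        kind, index, sense = _classify(J)
        found.append(FixedPoint((float(p[0]), float(p[1])), kind, J,
                                index, sense))
    return found


def regime_features(field: VelocityField,
                    axis_window: tuple[float, float] | None = None,
                    axis_tol: float | None = None,
                    turning_band: tuple[float, float] = (5.0, 30.0),
                    turning_threshold: float = 0.15) -> RegimeFeatures:
    """Aggregate fixed points into the regime discriminator features.

    The turning flow is probed in a region posterior to the axis sink and
    off the midline: the mean velocity component tangential to rays from
    the sink, normalized by the mean speed, measures how strongly the flow
    deviates from pure radial inflow (a lone sink gives exactly zero).
    Its sign is the turning orientation.

    Parameters
    ----------
    axis_window : (y_min, y_max) range along the midline in which features
        are counted; defaults to the full grid.
    axis_tol : distance from the midline below which a fixed point counts
        as on-axis; defaults to 1.5 grid spacings.
    turning_band : (lo, hi) extent of the probe region posterior to the
        sink, in grid spacings: ``y − y_sink`` within ``(lo, hi)`` spacings
        and ``x`` within ``(axis_tol, 25)`` spacings.
    turning_threshold : minimum |signed tangential fraction| for a turning
        flow to be present.
    """
    x, y = field.x, field.y
    dx = float(x[1] - x[0])
    dy = float(y[1] - y[0])
    if axis_tol is None:
        axis_tol = 1.5 * max(dx, dy)
    if axis_window is None:
        axis_window = (float(y[0]), float(y[-1]))

    fps = find_fixed_points(field)
    fps = [f for f in fps if axis_window[0] <= f.position[1] <= axis_window[1]]

    on_axis = [f for f in fps if abs(f.position[0]) <= axis_tol]
    off_axis_right = [f for f in fps if f.position[0] > axis_tol]

    has_ext = any(f.kind == "extension_point" for f in on_axis)
    sinks = [f for f in on_axis if f.kind == "sink_node"]
    has_sink = bool(sinks)

    vortices = [f for f in off_axis_right if f.kind == "center_vortex"]
    has_vortex = bool(vortices)
    vortex_orientation = None
    if has_vortex:
        strongest = max(vortices,
                        key=lambda f: abs(f.jacobian[1, 0] - f.jacobian[0, 1]))
        vortex_orientation = strongest.rotation_sense

    turning = None
    if has_sink:
        y_s = max(s.position[1] for s in sinks)
        X, Y = field.grid.meshgrid()
        step = max(dx, dy)
        band_lo = y_s + turning_band[0] * step
        band_hi = y_s + turning_band[1] * step
        probe = (field.mask & (Y >= band_lo) & (Y <= band_hi)
                 & (X > axis_tol) & (X <= 25 * step))
        if np.any(probe):
            rx = X[probe]
            ry = Y[probe] - y_s
            rn = np.hypot(rx, ry)
            rn = np.where(rn > 1e-12, rn, 1.0)
            # tangential unit vector of rays from the sink
            tx, ty = -ry / rn, rx / rn
            ut = field.u[probe] * tx + field.v[probe] * ty
            sp = np.hypot(field.u[probe], field.v[probe])
            frac = float(np.mean(ut) / max(np.mean(sp), 1e-300))
            if abs(frac) > turning_threshold:
                turning = int(np.sign(frac))

    return RegimeFeatures(has_vortex, vortex_orientation, has_ext,
                          has_sink, turning)


def match_regime(features: RegimeFeatures,
                 reference: RegimeFeatures) -> tuple[bool, dict]:
    """Feature-by-feature comparison against a reference regime.

    Returns ``(matches, diff)`` where ``diff`` maps feature names to
    ``(observed, expected)`` pairs for every mismatch.
    """
    fa = features.as_dict()
    fb = reference.as_dict()
    diff = {k: (fa[k], fb[k]) for k in fa if fa[k] != fb[k]}
    return (not diff), diff
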