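"""Strain-rate kinematics of the planar tissue flow.

The diagonal strain rates along the AP and left-right axes are

    ε_AP = ∂v/∂y,      ε_LR = ∂u/∂x,

with x, y the LR and AP coordinates and u, v the velocities in those
directions.  Positive values are stretch, negative compression.  The full
2D tensor (shear terms) is deliberately out of scope: only the two
diagonal components enter the analysis.

Derivatives use central finite differences over neighbouring domains
(one-sided at the borders), matching the ~40 µm domain lattice of the
flow quantification.
"""

from __future__ import annotations

import numpy as np

from .fields import VelocityField

__all__ = ["StrainField", "compute_strain", "max_abs_strain",
           "average_strain"]


class StrainField:
    """Diagonal strain-rate grids (1/min) on the source field's lattice."""

    def __init__(self, grid, eps_ap: np.ndarray, eps_lr: np.ndarray,
                 mask: np.ndarray | None = None,
                 time: float = float("nan")):
        self.grid = grid
        self.eps_ap = np.asarray(eps_ap, dtype=float)
        self.eps_lr = np.asarray(eps_lr, dtype=float)
        if self.eps_ap.shape != grid.shape or self.eps_lr.shape != grid.shape:
            raise ValueError("strain grids must match the grid shape")
        self.mask = (np.ones(grid.shape, dtype=bool) if mask is None
                     else np.asarray(mask, dtype=bool))
        self.time = time
        if not np.all(np.isfinite(self.eps_ap[self.mask])) or \
                not np.all(np.isfinite(self.eps_lr[self.mask])):
            raise ValueError("strain must be finite on the mask")


def compute_strain(field: VelocityField) -> StrainField:
    """Central-difference strain rates of a velocity field.

    Second-order accurate in the interior, one-sided at borders.
    """
    ny, nx = field.grid.shape
    if ny < 3 or nx < 3:
        raise ValueError("grid must be at least 3x3")
    dx, dy = field.grid.spacing
    eps_lr = np.gradient(field.u, dx, axis=1)
    eps_ap = np.gradient(field.v, dy, axis=0)
    return StrainField(field.grid, eps_ap, eps_lr, field.mask, field.time)


def max_abs_strain(strain: StrainField,
                   region: np.ndarray | None = None
                   ) -> tuple[float, float]:
    """Signed extremum of |ε| per axis within a region.

    Returns ``(eps_ap_extremum, eps_lr_extremum)``; each is the strain
    value of largest magnitude, reported with its sign (negative values
    indicate compression).
    """
    mask = strain.mask if region is None else strain.mask & region
    if not np.any(mask):
        raise ValueError("empty region")
    out = []
    for eps in (strain.eps_ap, strain.eps_lr):
        vals = eps[mask]
        out.append(float(vals[np.argmax(np.abs(vals))]))
    return tuple(out)


def average_strain(fields: list[VelocityField], time: float,
                   window: float = 15.0) -> StrainField:
    """Time-averaged strain over fields within ``[t − w/2, t + w/2]`` min.

    Reuses the flow-averaging window (15 min default).
    """
    sel = [f for f in fields if abs(f.time - time) <= window / 2]
    if not sel:
        raise ValueError("no fields inside the averaging window")
    strains = [compute_strain(f) for f in sel]
    mask = np.logical_and.reduce([s.mask for s in strains])
    eps_ap = np.mean([s.eps_ap for s in strains], axis=0)
    eps_lr = np.mean([s.eps_lr for s in strains], axis=0)
    return StrainField(sel[0].grid, eps_ap, eps_lr, mask, time)
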