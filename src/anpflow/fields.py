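"""Gridded planar velocity fields and particle tracks.

Coordinate conventions used throughout the package:

* ``x`` is the mediolateral (ML) axis, with the dorsal midline at ``x = 0``
  (negative left, positive right);
* ``y`` is the anteroposterior (AP) axis, with the anterior tissue limit at
  ``y = 0`` and positive values pointing posterior;
* velocities ``u`` (ML) and ``v`` (AP) are in µm/min;
* time is in hours post fertilisation (hpf).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np


@dataclass(frozen=True)
class GridSpec:
    """Regular planar lattice on which velocity fields are sampled."""

    x: np.ndarray  # 1D, µm, strictly increasing
    y: np.ndarray  # 1D, µm, strictly increasing

    def __post_init__(self):
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        for name, arr in (("x", self.x), ("y", self.y)):
            if arr.ndim != 1 or arr.size < 2:
                raise ValueError(f"grid {name} must be 1D with >= 2 samples")
            if not np.all(np.diff(arr) > 0):
                raise ValueError(f"grid {name} must be strictly increasing")

    @classmethod
    def centered(cls, half_width: float, y_min: float, y_max: float,
                 spacing: float) -> "GridSpec":
        """Midline-symmetric grid: x in [-half_width, half_width]."""
        nx = int(round(half_width / spacing))
        x = np.arange(-nx, nx + 1) * spacing
        y = np.arange(y_min, y_max + 0.5 * spacing, spacing)
        return cls(x, y)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.y.size, self.x.size)

    @property
    def spacing(self) -> tuple[float, float]:
        return (float(self.x[1] - self.x[0]), float(self.y[1] - self.y[0]))

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.x, self.y)

    def points(self) -> np.ndarray:
        """All lattice points as an (N, 2) array (x, y), row-major in y."""
        X, Y = self.meshgrid()
        return np.column_stack([X.ravel(), Y.ravel()])


@dataclass
class VelocityField:
    """A gridded 2D tissue flow with validity mask and timestamp.

    Arrays are indexed ``[iy, ix]`` (rows = y, columns = x).
    """

    grid: GridSpec
    u: np.ndarray  # ML velocity, µm/min
    v: np.ndarray  # AP velocity, µm/min
    mask: np.ndarray | None = None  # True where valid
    time: float = float("nan")  # hpf

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.u.shape != self.grid.shape or self.v.shape != self.grid.shape:
            raise ValueError(
                f"u/v shape {self.u.shape}/{self.v.shape} does not match grid "
                f"shape {self.grid.shape}")
        if self.mask is None:
            self.mask = np.ones(self.grid.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.grid.shape:
                raise ValueError("mask shape does not match grid shape")
        if not np.all(np.isfinite(self.u[self.mask])) or \
                not np.all(np.isfinite(self.v[self.mask])):
            raise ValueError("u, v must be finite wherever mask is True")

    @property
    def x(self) -> np.ndarray:
        return self.grid.x

    @property
    def y(self) -> np.ndarray:
        return self.grid.y

    @property
    def speed(self) -> np.ndarray:
        return np.hypot(self.u, self.v)

    def rms_speed(self) -> float:
        s = self.speed[self.mask]
        return float(np.sqrt(np.mean(s ** 2))) if s.size else 0.0

    def copy(self) -> "VelocityField":
        return VelocityField(self.grid, self.u.copy(), self.v.copy(),
                             self.mask.copy(), self.time)

    def __add__(self, other: "VelocityField") -> "VelocityField":
        if other.grid.shape != self.grid.shape:
            raise ValueError("grids differ")
        return VelocityField(self.grid, self.u + other.u, self.v + other.v,
                             self.mask & other.mask, self.time)

    def plot(self, ax=None, step: int = 1, **quiver_kw):
        """Quiver plot of the flow (x right, anterior up)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        X, Y = self.grid.meshgrid()
        s = slice(None, None, step)
        u = np.where(self.mask, self.u, np.nan)
        v = np.where(self.mask, self.v, np.nan)
        ax.quiver(X[s, s], Y[s, s], u[s, s], v[s, s], **quiver_kw)
        ax.set_xlabel("x (mediolateral, µm)")
        ax.set_ylabel("y (anteroposterior, µm)")
        ax.invert_yaxis()          # anterior (y = 0) at the top
        ax.set_aspect("equal")
        return ax


@dataclass
class Track:
    """One particle/cell trajectory; ``t`` strictly increasing."""

    track_id: int
    t: np.ndarray  # min (or hpf-derived minutes), strictly increasing
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray | None = None
    truncated: bool = False  # particle left the grid during advection

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.z is None:
            self.z = np.zeros_like(self.x)
        else:
            self.z = np.asarray(self.z, dtype=float)
        if not (self.t.shape == self.x.shape == self.y.shape == self.z.shape):
            raise ValueError("track coordinate arrays must share shape")
        if self.t.size >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValueError("track timestamps must be strictly increasing")

    def points(self) -> np.ndarray:
        return np.column_stack([self.x, self.y, self.z])


@dataclass
class TrackSet:
    tracks: list[Track] = field(default_factory=list)

    def __iter__(self):
        return iter(self.tracks)

    def __len__(self):
        return len(self.tracks)

    def __getitem__(self, i):
        return self.tracks[i]
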