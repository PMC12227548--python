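"""Regularized force and sink singularities driving the planar tissue flow.

Forces and sinks live on the dorsal midline (``x = 0``) at a distance
``position_d`` (µm) from the anterior tissue limit, measured along the AP
axis.  Each singularity is smeared over a finite ``extent`` (the standard
deviation of an isotropic Gaussian kernel) representing the physical area
over which the force or internalisation flux is applied to the tissue.

Force ``direction`` is the in-plane angle of the force vector, with 0
pointing posterior (+y) and π pointing anterior (−y); positive angles turn
toward +x.  Magnitudes, sink strengths and the friction coefficient γ² are
in arbitrary units with the tissue viscosity normalized to 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class ForceSingularity:
    position_d: float          # µm from the anterior limit, along the axis
    direction: float           # rad; 0 = +y (posterior), pi = anterior
    magnitude: float           # AU, >= 0
    extent: float              # µm, Gaussian regularization s.d., > 0
    position_x: float = 0.0    # off-axis offset; 0 unless off-axis fitting

    def __post_init__(self):
        if self.extent <= 0:
            raise ValueError("force extent must be > 0")
        if not np.isfinite(self.magnitude) or self.magnitude < 0:
            raise ValueError("force magnitude must be finite and >= 0")

    @property
    def position(self) -> np.ndarray:
        return np.array([self.position_x, self.position_d])

    @property
    def vector(self) -> np.ndarray:
        """Force vector (Fx, Fy)."""
        return self.magnitude * np.array(
            [np.sin(self.direction), np.cos(self.direction)])


@dataclass(frozen=True)
class SinkSingularity:
    position_d: float  # µm from the anterior limit
    strength: float    # Q, area flux removed per unit time, AU, >= 0
    extent: float      # µm, Gaussian regularization s.d., > 0
    position_x: float = 0.0

    def __post_init__(self):
        if self.extent <= 0:
            raise ValueError("sink extent must be > 0")
        if not np.isfinite(self.strength) or self.strength < 0:
            raise ValueError("sink strength must be finite and >= 0")

    @property
    def position(self) -> np.ndarray:
        return np.array([self.position_x, self.position_d])


@dataclass(frozen=True)
class SingularityConfig:
    """Forces, sinks and substrate friction of the mechanical model."""

    forces: tuple[ForceSingularity, ...] = ()
    sinks: tuple[SinkSingularity, ...] = ()
    gamma2: float = 0.01   # EVL-neuroectoderm friction coefficient, 1/µm²
    viscosity: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "forces", tuple(self.forces))
        object.__setattr__(self, "sinks", tuple(self.sinks))
        if self.gamma2 < 0 or not np.isfinite(self.gamma2):
            raise ValueError("gamma2 must be finite and >= 0")
        if self.viscosity <= 0:
            raise ValueError("viscosity must be > 0")

    def __or__(self, other: "SingularityConfig") -> "SingularityConfig":
        """Superposition of two configs sharing friction and viscosity."""
        if not np.isclose(self.gamma2, other.gamma2) or \
                not np.isclose(self.viscosity, other.viscosity):
            raise ValueError("can only combine configs with equal gamma2 "
                             "and viscosity")
        return SingularityConfig(self.forces + other.forces,
                                 self.sinks + other.sinks,
                                 self.gamma2, self.viscosity)

    def scaled(self, factor: float) -> "SingularityConfig":
        """Scale all magnitudes and sink strengths by ``factor``."""
        return SingularityConfig(
            tuple(ForceSingularity(f.position_d, f.direction,
                                   f.magnitude * factor, f.extent,
                                   f.position_x) for f in self.forces),
            tuple(SinkSingularity(s.position_d, s.strength * factor,
                                  s.extent, s.position_x)
                  for s in self.sinks),
            self.gamma2, self.viscosity)

    # -- JSON round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "forces": [asdict(f) for f in self.forces],
            "sinks": [asdict(s) for s in self.sinks],
            "gamma2": self.gamma2,
            "viscosity": self.viscosity,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SingularityConfig":
        return cls(
            tuple(ForceSingularity(**f) for f in d.get("forces", [])),
            tuple(SinkSingularity(**s) for s in d.get("sinks", [])),
            float(d.get("gamma2", 0.01)),
            float(d.get("viscosity", 1.0)),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SingularityConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))
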