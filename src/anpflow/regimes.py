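"""Canonical qualitative singularity configurations and their flow regimes.

The mechanical model discriminates candidate force arrangements by the
topology of the flow they generate.  This module encodes the standard panel
of candidate configurations — single and paired midline forces before
internalisation, and sink/force combinations after internalisation — with
a shared geometry chosen to resemble the anterior neural plate: an AP
domain of ~300 µm with the anterior limit at y = 0, forces and the sink on
the dorsal midline, regularization extents of a few cell diameters, and a
friction screening length (1/γ) of ~25 µm so lateral vortices sit ~50 µm
off the midline.

The experimental reference regimes are *derived* from the symmetrised
flows of the configurations that reproduce the observations (opposing
forces with the anterior-directed one dominant before internalisation;
sink plus anterior-directed drag after), not hard-coded feature vectors:
the harness therefore tests consistency between configurations rather
than an absolute vortex sense.
"""

from __future__ import annotations

import numpy as np

from .brinkman import evaluate_model
from .fields import GridSpec, VelocityField
from .singularities import (ForceSingularity, SingularityConfig,
                            SinkSingularity)
from .topology import RegimeFeatures, regime_features

__all__ = ["PANELS", "panel_config", "panel_field", "default_grid",
           "reference_features", "PANEL_CLAIMS"]

ANTERIOR = np.pi   # force direction pointing anterior (−y)
POSTERIOR = 0.0    # force direction pointing posterior (+y)

_GAMMA2 = 0.0015   # 1/µm²; screening length ≈ 26 µm
_EXT_F = 25.0      # µm force regularization extent
_EXT_S = 20.0      # µm sink regularization extent
_Q = 150.0         # sink strength, AU

_F = ForceSingularity
_S = SinkSingularity

#: Candidate configurations, keyed by a descriptive regime name.
PANELS: dict[str, SingularityConfig] = {
    # --- before internalisation: forces only ------------------------------
    "single_anterior_force": SingularityConfig(
        forces=(_F(110.0, ANTERIOR, 10.0, _EXT_F),), gamma2=_GAMMA2),
    "two_parallel_forces": SingularityConfig(
        forces=(_F(80.0, ANTERIOR, 10.0, _EXT_F),
                _F(140.0, ANTERIOR, 10.0, _EXT_F)), gamma2=_GAMMA2),
    "antiparallel_posterior_dominant": SingularityConfig(
        forces=(_F(40.0, POSTERIOR, 16.0, _EXT_F),
                _F(170.0, ANTERIOR, 8.0, _EXT_F)), gamma2=_GAMMA2),
    "antiparallel_anterior_dominant": SingularityConfig(
        forces=(_F(40.0, POSTERIOR, 8.0, _EXT_F),
                _F(170.0, ANTERIOR, 16.0, _EXT_F)), gamma2=_GAMMA2),
    # --- after internalisation: sink + forces -----------------------------
    "lone_sink": SingularityConfig(
        sinks=(_S(110.0, _Q, _EXT_S),), gamma2=_GAMMA2),
    "sink_plus_pull": SingularityConfig(
        forces=(_F(190.0, POSTERIOR, 20.0, _EXT_F),),
        sinks=(_S(110.0, _Q, _EXT_S),), gamma2=_GAMMA2),
    "sink_plus_drag": SingularityConfig(
        forces=(_F(190.0, ANTERIOR, 20.0, _EXT_F),),
        sinks=(_S(110.0, _Q, _EXT_S),), gamma2=_GAMMA2),
    "sink_drag_and_small_pull": SingularityConfig(
        forces=(_F(190.0, ANTERIOR, 20.0, _EXT_F),
                _F(40.0, POSTERIOR, 8.0, _EXT_F)),
        sinks=(_S(110.0, _Q, _EXT_S),), gamma2=_GAMMA2),
}

#: The qualitative claims each panel must exhibit, as (feature, value)
#: constraints; vortex/turning senses are relative to the reference panels
#: ``antiparallel_anterior_dominant`` and ``sink_plus_drag``.
PANEL_CLAIMS: dict[str, dict] = {
    "single_anterior_force": {
        "has_vortex": True, "has_extension_point_on_axis": False},
    "two_parallel_forces": {
        "has_vortex": True, "has_extension_point_on_axis": False},
    "antiparallel_posterior_dominant": {
        "has_extension_point_on_axis": True,
        "vortex_sense_vs_reference": "opposite"},
    "antiparallel_anterior_dominant": {
        "has_extension_point_on_axis": True, "has_vortex": True},
    "lone_sink": {
        "has_axis_sink": True, "turning_flow_orientation": None},
    "sink_plus_pull": {
        "has_axis_sink": True, "turning_sense_vs_reference": "opposite"},
    "sink_plus_drag": {
        "has_axis_sink": True, "turning_present": True},
    "sink_drag_and_small_pull": {
        "has_axis_sink": True, "turning_sense_vs_reference": "same"},
}


def default_grid(n: int = 96) -> GridSpec:
    """The standard evaluation grid: ±150 µm ML, −40..260 µm AP."""
    return GridSpec(np.linspace(-150.0, 150.0, n),
                    np.linspace(-40.0, 260.0, n))


def panel_config(name: str) -> SingularityConfig:
    return PANELS[name]


def panel_field(name: str, grid: GridSpec | None = None) -> VelocityField:
    return evaluate_model(PANELS[name], grid or default_grid())


def reference_features(stage: str, grid: GridSpec | None = None
                       ) -> RegimeFeatures:
    """Reference regime for a developmental stage.

    ``stage`` is ``"before_internalisation"`` (opposing forces, anterior
    dominant) or ``"after_internalisation"`` (sink + anterior drag).
    """
    key = {"before_internalisation": "antiparallel_anterior_dominant",
           "after_internalisation": "sink_plus_drag"}[stage]
    return regime_features(panel_field(key, grid))
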