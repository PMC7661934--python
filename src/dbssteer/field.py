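"""Extracellular potential model.

The electric potential around the lead is computed by analytic point-source
superposition in an infinite homogeneous medium of conductivity sigma_bulk:

    V(x) = sum_k I_k / (4 pi sigma |x - x_k|)

with each contact discretized into weighted surface point sources.  Cathodic
stimulation carries negative current, so potentials are negative near the
lead.  The model deliberately omits the encapsulation layer and the insulating
shaft from the field computation; the encapsulation enters downstream only as
the inner radial margin of the axon lattice, and impedance values enter only
the battery-current model, which is decoupled from the field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .lead import LeadGeometry, electrode_surface_points

__all__ = ["TissueModel", "SourceConfiguration", "make_sources", "potential_at",
           "export_potential_csv"]

_MIN_DISTANCE_MM = 1e-9


@dataclass(frozen=True)
class TissueModel:
    """Tissue electrical parameters (conductivities in S/m, thickness in um)."""

    bulk_conductivity: float = 0.2
    encapsulation_thickness_um: float = 500.0
    encapsulation_conductivity: float = 0.1

    def __post_init__(self) -> None:
        if self.bulk_conductivity <= 0 or self.encapsulation_conductivity <= 0:
            raise ValueError("conductivities must be positive")
        if self.encapsulation_thickness_um < 0:
            raise ValueError("encapsulation thickness must be >= 0")


@dataclass
class SourceConfiguration:
    """Point-source decomposition of a stimulation setting.

    ``electrode_amplitudes_mA`` maps electrode index to its signed amplitude
    (negative = cathodic); ``positions``/``currents_mA`` hold the per-point
    decomposition, with point currents summing to each electrode's amplitude.
    """

    positions: np.ndarray              # (n, 3) mm
    currents_mA: np.ndarray            # (n,) signed mA
    electrode_amplitudes_mA: dict[int, float]
    geometry: LeadGeometry | None = None
    z_center: float | None = None      # vertical centre of activated electrodes
    metadata: dict = field(default_factory=dict)

    @property
    def total_amplitude_mA(self) -> float:
        """Total cathodic amplitude magnitude in mA."""
        return float(sum(abs(a) for a in self.electrode_amplitudes_mA.values()))


def make_sources(geometry: LeadGeometry, distribution: Mapping[int, float],
                 total_amplitude_mA: float, n_per_axis: int = 4) -> SourceConfiguration:
    """Fractionalize a total cathodic amplitude across electrodes.

    ``distribution`` maps electrode index to a signed percentage (e.g.
    ``{2: -70, 3: -30}``); magnitudes must sum to 100%.  Each electrode's
    amplitude is its fraction of ``total_amplitude_mA``, conserved exactly
    across its surface points.
    """
    mags = [abs(v) for v in distribution.values()]
    if abs(sum(mags) - 100.0) > 1e-9:
        raise ValueError(f"fraction magnitudes must sum to 100%, got {sum(mags)}")
    if total_amplitude_mA < 0:
        raise ValueError("total amplitude is a magnitude, must be >= 0")

    pos_parts, cur_parts = [], []
    amplitudes: dict[int, float] = {}
    zs = []
    for e, pct in distribution.items():
        amp = -(abs(pct) / 100.0) * total_amplitude_mA  # cathodic: negative
        amplitudes[int(e)] = amp
        p, w = electrode_surface_points(geometry, e, n_per_axis)
        pos_parts.append(p)
        cur_parts.append(amp * w)
        if abs(pct) > 0:
            zs.append(geometry.level_of(e).z_center)
    positions = np.vstack(pos_parts) if pos_parts else np.empty((0, 3))
    currents = np.concatenate(cur_parts) if cur_parts else np.empty(0)
    z_center = float(np.mean(zs)) if zs else None
    return SourceConfiguration(
        positions, currents, amplitudes, geometry=geometry, z_center=z_center,
        metadata={"field_model": "point-source superposition, homogeneous medium",
                  "encapsulation_in_field": False})


def potential_at(points: np.ndarray, sources: SourceConfiguration,
                 tissue: TissueModel) -> np.ndarray:
    """Potential in volts at ``points`` (..., 3) mm.

    Raises if a query point coincides with a source point.
    """
    pts = np.asarray(points, dtype=float)
    out_shape = pts.shape[:-1]
    pts = pts.reshape(-1, 3)
    if sources.positions.shape[0] == 0:
        return np.zeros(out_shape)
    # squared distances via the expanded form (BLAS matmul); mm units
    sp = sources.positions
    d2 = ((pts ** 2).sum(1)[:, None] + (sp ** 2).sum(1)[None, :]
          - 2.0 * pts @ sp.T)
    np.maximum(d2, 0.0, out=d2)
    d = np.sqrt(d2)
    if np.any(d < _MIN_DISTANCE_MM):
        raise ValueError("query point coincides with a source point")
    # currents mA -> A, distances mm -> m
    v = (sources.currents_mA[None, :] * 1e-3) / (
        4.0 * np.pi * tissue.bulk_conductivity * d * 1e-3)
    return v.sum(axis=1).reshape(out_shape)


def export_potential_csv(path, points: np.ndarray, sources: SourceConfiguration,
                         tissue: TissueModel) -> None:
    """Write ``x,y,z,V`` rows for inspection."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    v = potential_at(pts, sources, tissue)
    arr = np.column_stack([pts, v])
    np.savetxt(path, arr, delimiter=",", header="x_mm,y_mm,z_mm,V", comments="")
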