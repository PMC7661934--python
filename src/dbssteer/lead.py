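"""Directional DBS lead geometry.

Models an eight-contact 1-3-3-1 segmented lead (Boston Scientific 2202-class):
a ring contact at the tip, two directional levels of three segments each, and a
ring contact at the top.  The angular frame is anchored to the orientation
marker: electrode 2 is centred at 0 deg and the positive direction points
toward electrode 3 (at +120 deg), so two-electrode steering between E2 and E3
spans expected rotation angles of 0-60 deg.

All lengths are in millimetres, all angles in degrees.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np

__all__ = [
    "ElectrodeID",
    "ContactLevel",
    "LeadGeometry",
    "build_default_lead",
    "electrode_surface_points",
    "rotated_geometry",
]


@dataclass(frozen=True)
class ElectrodeID:
    """A contact identified by its 1-based index and level ('ring' or level number)."""

    index: int
    level: int | str = "ring"

    def __post_init__(self) -> None:
        if not 1 <= self.index <= 8:
            raise ValueError(f"electrode index must be in 1..8, got {self.index}")


@dataclass
class ContactLevel:
    """One vertical level of contacts.

    ``kind='ring'`` levels hold a single full-circumference contact;
    ``kind='directional'`` levels hold exactly three segments whose angular
    centres are 120 deg apart.
    """

    z_center: float
    electrode_ids: tuple[int, ...]
    angular_centers: tuple[float, ...]
    angular_span: float
    kind: str = "directional"

    def validate(self) -> None:
        if self.kind == "directional":
            if len(self.electrode_ids) != 3:
                raise ValueError("directional levels contain exactly 3 electrodes")
            c = np.asarray(self.angular_centers, dtype=float)
            gaps = np.diff(np.sort(c % 360.0))
            if not np.allclose(gaps, 120.0, atol=1e-9):
                raise ValueError("directional angular centers must be 120 deg apart")
            if not (0.0 < self.angular_span < 120.0):
                raise ValueError("angular_span must lie in (0, 120) deg")
        elif self.kind == "ring":
            if len(self.electrode_ids) != 1:
                raise ValueError("ring levels hold a single contact")
        else:
            raise ValueError(f"unknown level kind {self.kind!r}")


@dataclass
class LeadGeometry:
    """Segmented-lead geometry in a cylindrical frame aligned with the shaft (z axis)."""

    shaft_radius: float = 0.65
    contact_height: float = 1.5
    intercontact_gap: float = 0.5
    levels: list[ContactLevel] = field(default_factory=list)
    marker_angle: float = 0.0

    def __post_init__(self) -> None:
        if self.shaft_radius <= 0 or self.contact_height <= 0:
            raise ValueError("shaft_radius and contact_height must be positive")
        z = [lv.z_center for lv in self.levels]
        if any(b <= a for a, b in zip(z, z[1:])):
            raise ValueError("level z_centers must be strictly increasing from the tip")
        seen: set[int] = set()
        for lv in self.levels:
            lv.validate()
            for e in lv.electrode_ids:
                if e in seen:
                    raise ValueError(f"duplicate electrode index {e}")
                seen.add(e)

    # -- lookups ---------------------------------------------------------

    def level_of(self, electrode: int | ElectrodeID) -> ContactLevel:
        idx = electrode.index if isinstance(electrode, ElectrodeID) else int(electrode)
        for lv in self.levels:
            if idx in lv.electrode_ids:
                return lv
        raise KeyError(f"unknown electrode id {idx}")

    def angular_center(self, electrode: int | ElectrodeID) -> float:
        idx = electrode.index if isinstance(electrode, ElectrodeID) else int(electrode)
        lv = self.level_of(idx)
        if lv.kind == "ring":
            return 0.0
        return float(lv.angular_centers[lv.electrode_ids.index(idx)])

    def directional_electrodes(self) -> list[int]:
        out: list[int] = []
        for lv in self.levels:
            if lv.kind == "directional":
                out.extend(lv.electrode_ids)
        return out

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "LeadGeometry":
        levels = [ContactLevel(**{**lv,
                                  "electrode_ids": tuple(lv["electrode_ids"]),
                                  "angular_centers": tuple(lv["angular_centers"])})
                  for lv in d["levels"]]
        return cls(shaft_radius=d["shaft_radius"], contact_height=d["contact_height"],
                   intercontact_gap=d["intercontact_gap"], levels=levels,
                   marker_angle=d.get("marker_angle", 0.0))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "LeadGeometry":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def build_default_lead(shaft_radius: float = 0.65, contact_height: float = 1.5,
                       intercontact_gap: float = 0.5, angular_span: float = 90.0,
                       ) -> LeadGeometry:
    """Build the default 1-3-3-1 directional lead.

    Contact dimensions are configurable 2202-class defaults.  Electrode 2 is
    centred at 0 deg, electrode 3 at +120 deg and electrode 4 at +240 deg on
    the first directional level; electrodes 5-7 mirror them on the second.
    """
    pitch = contact_height + intercontact_gap
    z0 = contact_height / 2.0
    levels = [
        ContactLevel(z0, (1,), (0.0,), 360.0, kind="ring"),
        ContactLevel(z0 + pitch, (2, 3, 4), (0.0, 120.0, 240.0), angular_span),
        ContactLevel(z0 + 2 * pitch, (5, 6, 7), (0.0, 120.0, 240.0), angular_span),
        ContactLevel(z0 + 3 * pitch, (8,), (0.0,), 360.0, kind="ring"),
    ]
    return LeadGeometry(shaft_radius, contact_height, intercontact_gap, levels)


def electrode_surface_points(geometry: LeadGeometry, electrode: int | ElectrodeID,
                             n_per_axis: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Discretize one contact into weighted surface point sources.

    Returns ``(positions, weights)`` where positions is ``(n, 3)`` in mm on the
    contact's cylindrical patch and weights sum to 1.  ``n_per_axis=1`` yields
    the single contact-centre point.
    """
    if n_per_axis < 1:
        raise ValueError("n_per_axis must be >= 1")
    lv = geometry.level_of(electrode)
    center_deg = geometry.angular_center(electrode)
    span = lv.angular_span
    # cell-centred offsets, symmetric about the contact centre
    u = (np.arange(n_per_axis) + 0.5) / n_per_axis - 0.5
    ang = np.deg2rad(center_deg + span * u)
    zz = lv.z_center + geometry.contact_height * u
    A, Z = np.meshgrid(ang, zz, indexing="ij")
    r = geometry.shaft_radius
    pos = np.column_stack([r * np.cos(A).ravel(), r * np.sin(A).ravel(), Z.ravel()])
    w = np.full(pos.shape[0], 1.0 / pos.shape[0])
    return pos, w


def rotated_geometry(geometry: LeadGeometry, angle_deg: float) -> LeadGeometry:
    """Return a copy of the geometry rotated about the shaft by ``angle_deg``."""
    levels = [ContactLevel(lv.z_center, lv.electrode_ids,
                           tuple((c + angle_deg) % 360.0 for c in lv.angular_centers),
                           lv.angular_span, lv.kind)
              for lv in geometry.levels]
    return LeadGeometry(geometry.shaft_radius, geometry.contact_height,
                        geometry.intercontact_gap, levels,
                        (geometry.marker_angle + angle_deg) % 360.0)
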