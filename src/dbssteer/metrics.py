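"""Steering metrics on VTAs.

Rotation angle (equal-area bisector searched in 1-degree steps), VTA radius
along a direction, deviation from the linear-proportion expected rotation
angle, voxel volume, and overlap percentages.  Cross-sections are polar
rasters at 1 degree x 0.05 mm taken at the vertical centre of the activated
electrodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .polar import (circular_difference, equal_area_angle, radius_at_angle,
                    polar_area)
from .vta import VTA

__all__ = [
    "CrossSection", "cross_section", "equal_area_bisector", "vta_radius",
    "expected_rotation_angle", "rotation_deviation", "vta_volume",
    "overlap_percent", "rotated_cross_section", "export_cross_section_csv",
]

DEFAULT_RADIAL_STEP = 0.05  # mm
DEFAULT_ANGLE_STEP = 1.0    # deg


@dataclass
class CrossSection:
    """Polar occupancy raster of a VTA slice.

    ``occupancy[k, j]`` samples the angular bin ``[k, k+1)`` degrees at radial
    centre ``r_centers[j]`` mm; ``radial_step`` is the constant radial bin
    width.
    """

    z_plane: float
    occupancy: np.ndarray            # bool (360, n_r)
    r_centers: np.ndarray            # (n_r,)
    radial_step: float = DEFAULT_RADIAL_STEP
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, bool)
        self.r_centers = np.asarray(self.r_centers, float)
        if self.occupancy.shape != (360, self.r_centers.size):
            raise ValueError("occupancy must be (360, n_r)")
        if np.any(self.r_centers < 0):
            raise ValueError("radial samples must be non-negative")

    @property
    def is_empty(self) -> bool:
        return not self.occupancy.any()

    def area_mm2(self) -> float:
        return polar_area(self.occupancy, self.r_centers, self.radial_step)


def cross_section(vta: VTA, z_plane: float | None = None,
                  radial_step: float = DEFAULT_RADIAL_STEP,
                  r_max: float | None = None) -> CrossSection:
    """Polar resampling of a VTA at ``z_plane`` (defaults to the VTA's centre).

    For lattice-built VTAs membership is tested against the continuous
    activated region (union of half-spacing balls around active axon nodes),
    which is exactly symmetric under the lattice's mirror symmetries; VTAs
    defined only by voxels fall back to voxel lookup.  An empty slice yields
    an empty (flagged) cross-section.
    """
    if z_plane is None:
        lo, hi = vta.z_extent()
        z_plane = 0.5 * (lo + hi)
    lo, hi = vta.z_extent()
    if not (lo <= z_plane <= hi):
        raise ValueError("z_plane outside VTA extent")
    if r_max is None:
        # cover the voxel grid's xy-corners (farthest possible occupied point)
        xs = (vta.origin[0], vta.origin[0]
              + vta.occupancy.shape[0] * vta.voxel_resolution)
        ys = (vta.origin[1], vta.origin[1]
              + vta.occupancy.shape[1] * vta.voxel_resolution)
        r_max = float(max(np.hypot(x, y) for x in xs for y in ys))
    n_r = int(np.floor(r_max / radial_step))
    r_centers = (np.arange(n_r) + 0.5) * radial_step
    ang = np.deg2rad(np.arange(360.0) + 0.5)
    X = r_centers[None, :] * np.cos(ang)[:, None]
    Y = r_centers[None, :] * np.sin(ang)[:, None]
    pts = np.stack([X, Y, np.full_like(X, z_plane)], axis=-1).reshape(-1, 3)
    occ = vta.contains_points(pts).reshape(360, n_r)
    return CrossSection(z_plane, occ, r_centers, radial_step,
                        meta={"empty": not occ.any(),
                              "source": "points" if vta.active_points is not None
                              else "voxels"})


def equal_area_bisector(cs: CrossSection) -> float:
    """Direction (deg) of the 1-degree-step line splitting the section into
    equal areas; ties toward the smallest angle, direction disambiguated by
    the occupancy centroid.  Raises on an empty cross-section."""
    if cs.is_empty:
        raise ValueError("empty cross-section has no bisector")
    return equal_area_angle(cs.occupancy, cs.r_centers, cs.radial_step)


def vta_radius(cs: CrossSection, angle_deg: float) -> float:
    """Maximum occupied radial sample along ``angle_deg`` (0, flagged, if none)."""
    if not (0.0 <= angle_deg < 360.0):
        angle_deg = angle_deg % 360.0
    return radius_at_angle(cs.occupancy, cs.r_centers, angle_deg)


def expected_rotation_angle(distribution) -> float:
    """Linear-proportion expected rotation for a two-electrode fractionalization.

    The fraction on the secondary (higher-angle) adjacent segment times the
    120-degree inter-segment separation: -70/-30% -> 36 deg, -50/-50% -> 60 deg,
    -100/0% -> 0 deg.
    """
    items = [(int(e), abs(float(p))) for e, p in dict(distribution).items()]
    if len(items) != 2:
        raise ValueError("expected a two-electrode fractionalization")
    if abs(items[0][1] + items[1][1] - 100.0) > 1e-9:
        raise ValueError("fraction magnitudes must sum to 100%")
    e_lo, e_hi = sorted(items, key=lambda t: t[0])
    if e_hi[0] - e_lo[0] != 1:
        raise ValueError("electrodes must be adjacent segments")
    return e_hi[1] / 100.0 * 120.0


def rotation_deviation(measured_deg: float, expected_deg: float) -> float:
    """|measured - expected| on the circle (wrap-around aware)."""
    if not (np.isfinite(measured_deg) and np.isfinite(expected_deg)):
        raise ValueError("angles must be finite")
    return circular_difference(measured_deg, expected_deg)


def vta_volume(vta: VTA) -> float:
    """Voxel-count volume in mm^3."""
    return vta.volume_mm3


def overlap_percent(a: VTA, b: VTA) -> float:
    """100 * |a intersect b| / |b| on voxel counts."""
    if not a.same_grid(b):
        raise ValueError("VTAs must share resolution, origin and shape")
    nb = int(b.occupancy.sum())
    if nb == 0:
        raise ValueError("reference VTA is empty")
    return 100.0 * int((a.occupancy & b.occupancy).sum()) / nb


def rotated_cross_section(cs: CrossSection, delta_deg: int) -> CrossSection:
    """Rotate a cross-section by an integer number of degrees (bin roll)."""
    return CrossSection(cs.z_plane, np.roll(cs.occupancy, int(delta_deg), axis=0),
                        cs.r_centers, cs.radial_step, dict(cs.meta))


def export_cross_section_csv(cs: CrossSection, path) -> None:
    """Write (angle_deg, radius_mm, occupied) rows."""
    ang = np.repeat(np.arange(360), cs.r_centers.size)
    rad = np.tile(cs.r_centers, 360)
    occ = cs.occupancy.ravel().astype(int)
    arr = np.column_stack([ang, rad, occ])
    np.savetxt(path, arr, delimiter=",", fmt=["%d", "%.4f", "%d"],
               header="angle_deg,radius_mm,occupied", comments="")
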