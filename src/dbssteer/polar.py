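"""Polar occupancy helpers shared by the VTA engine and the steering metrics.

A polar occupancy raster is a boolean array of shape ``(360, n_r)`` sampled at
1-degree angular bins (bin ``k`` covers ``[k, k+1)`` degrees) and radial bin
centres ``r_centers`` (mm) with constant step ``dr``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["circular_difference", "equal_area_angle", "radius_at_angle",
           "polar_area"]


def circular_difference(a_deg: float, b_deg: float) -> float:
    """Absolute angular difference on the circle, in [0, 180]."""
    d = abs(float(a_deg) - float(b_deg)) % 360.0
    return min(d, 360.0 - d)


def polar_area(occ: np.ndarray, r_centers: np.ndarray, dr: float) -> float:
    """Occupied area in mm^2 (cells weighted by r * dr * dtheta)."""
    w = r_centers * dr * (np.pi / 180.0)
    return float(occ @ w).__abs__() if occ.ndim == 1 else float((occ @ w).sum())


def _angular_area_profile(occ: np.ndarray, r_centers: np.ndarray, dr: float) -> np.ndarray:
    w = r_centers * dr * (np.pi / 180.0)
    return occ @ w  # (360,)


def equal_area_angle(occ: np.ndarray, r_centers: np.ndarray, dr: float) -> float:
    """Equal-area bisector direction of a polar occupancy raster, in degrees.

    Searches line angles theta in {0..179} (1-degree steps) for the one that
    minimizes |A_left - A_right|, the areas on the two sides of the line
    through the axis; ties break toward the smallest angle.  Of the line's two
    directions (theta, theta+180) the one closer to the occupancy centroid is
    returned (ties toward the smaller angle).
    """
    occ = np.asarray(occ, bool)
    if occ.shape[0] != 360:
        raise ValueError("polar occupancy must have 360 angular bins")
    if not occ.any():
        raise ValueError("empty cross-section has no bisector")
    a = _angular_area_profile(occ, np.asarray(r_centers, float), dr)
    total = a.sum()
    cs = np.concatenate([[0.0], np.cumsum(np.concatenate([a, a]))])
    th = np.arange(180)
    a_left = cs[th + 180] - cs[th]
    theta = int(np.argmin(np.abs(2.0 * a_left - total)))  # argmin ties -> smallest

    # centroid direction (area-weighted first moment of the occupied cells)
    phi = np.deg2rad(np.arange(360) + 0.5)
    wr = occ @ (np.asarray(r_centers, float) ** 2 * dr * (np.pi / 180.0))
    cx, cy = float(wr @ np.cos(phi)), float(wr @ np.sin(phi))
    if cx == 0.0 and cy == 0.0:
        return float(theta)
    cang = np.rad2deg(np.arctan2(cy, cx)) % 360.0
    if circular_difference(theta, cang) <= circular_difference(theta + 180, cang):
        return float(theta)
    return float(theta + 180)


def radius_at_angle(occ: np.ndarray, r_centers: np.ndarray, angle_deg: float) -> float:
    """Maximum occupied radial sample along ``angle_deg`` (0 if none occupied)."""
    row = np.asarray(occ, bool)[int(np.floor(angle_deg)) % 360]
    if not row.any():
        return 0.0
    return float(np.asarray(r_centers, float)[row].max())
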