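"""Volume-of-tissue-activated (VTA) engine.

Binary VTAs are built from the point-source field model with an
activating-function threshold surrogate: straight myelinated axons run
perpendicular to the lead shaft (tangentially), arranged in half-planes every
30 degrees with 0.5 mm spacing; an axon is activated when the peak discrete
second difference of the extracellular potential along its nodes reaches a
scalar threshold.  The threshold is calibrated once so that a single-electrode
setting at a known anchor amplitude produces a known VTA radius.

Because the activating function is linear in the source amplitudes, the
active set grows monotonically with amplitude, MICC settings sum their fields
before thresholding, and Interleaving/MSS settings threshold each electrode's
field independently (the paradigms' defining difference).

Amplitude titration to a target radius bisects on the total amplitude and
measures the radius on a dense polar boundary (0.01 mm radial step, 1-degree
angular step) of the same field/threshold model, evaluated at the
electrode-centre cross-section along the equal-area bisector direction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from typing import Mapping

import numpy as np
from scipy.spatial import cKDTree

from .lead import LeadGeometry, build_default_lead
from .field import TissueModel, SourceConfiguration, make_sources, potential_at
from .polar import equal_area_angle, radius_at_angle

__all__ = [
    "AxonGridSpec", "ActivationModel", "VTA",
    "activating_function", "calibrate_threshold", "build_vta",
    "titrate_amplitude", "build_interleaving_vtas",
    "vta_union", "vta_intersection", "scan_radius_1d",
    "SteeringModel",
]


# ---------------------------------------------------------------------------
# domain types

@dataclass(frozen=True)
class AxonGridSpec:
    """Axon sampling lattice around the lead.

    Axons live in half-planes every ``plane_step_deg`` (covering a full turn),
    at radial/vertical positions spaced ``grid_spacing`` mm, oriented
    tangentially (perpendicular to the shaft), with ``nodes_per_axon`` nodes
    ``node_spacing`` mm apart.  ``inner_radial_margin`` excludes tissue inside
    the shaft + encapsulation from sampling.
    """

    plane_step_deg: float = 30.0
    grid_spacing: float = 0.5
    radial_extent: float = 6.0
    vertical_extent: float = 5.0
    node_spacing: float = 0.5
    nodes_per_axon: int = 21
    inner_radial_margin: float = 1.15

    def __post_init__(self) -> None:
        if self.grid_spacing <= 0 or self.node_spacing <= 0:
            raise ValueError("spacings must be positive")
        if self.nodes_per_axon < 3 or self.nodes_per_axon % 2 == 0:
            raise ValueError("nodes_per_axon must be odd and >= 3")
        if self.plane_step_deg <= 0 or abs(360.0 % self.plane_step_deg) > 1e-9:
            raise ValueError("plane angles must cover a full turn in equal steps")
        if self.radial_extent <= self.inner_radial_margin:
            raise ValueError("radial_extent must exceed inner_radial_margin")

    @property
    def plane_angles(self) -> np.ndarray:
        return np.arange(0.0, 360.0, self.plane_step_deg)

    @property
    def radial_positions(self) -> np.ndarray:
        n = int(np.floor((self.radial_extent - self.inner_radial_margin)
                         / self.grid_spacing)) + 1
        return self.inner_radial_margin + np.arange(n) * self.grid_spacing

    def vertical_positions(self, z_center: float) -> np.ndarray:
        m = int(np.floor(self.vertical_extent / self.grid_spacing))
        return z_center + np.arange(-m, m + 1) * self.grid_spacing


@dataclass
class ActivationModel:
    """Calibrated activation threshold on the peak activating function (volts)."""

    af_threshold: float
    calibration_anchor: dict = dc_field(default_factory=dict)
    axon_diameter_um: float = 5.7  # metadata: internal-capsule-class fibres

    def __post_init__(self) -> None:
        if self.af_threshold <= 0:
            raise ValueError("af_threshold must be positive")


@dataclass
class VTA:
    """Binary voxel occupancy volume with provenance.

    ``active_points`` (when present) are the activated axon-lattice node
    centres; the continuous activated region is the union of balls of radius
    ``stamp_radius`` around them, and ``occupancy`` marks voxels whose centres
    fall inside that region.  VTAs produced purely by voxel-set algebra carry
    ``active_points=None`` and are defined by their voxels alone.
    """

    voxel_resolution: float
    origin: np.ndarray                       # (3,) mm, corner of voxel (0,0,0)
    occupancy: np.ndarray                    # bool, shape (nx, ny, nz)
    active_points: np.ndarray | None = None  # (n, 3) mm
    stamp_radius: float = 0.25
    provenance: dict = dc_field(default_factory=dict)
    _tree: cKDTree | None = dc_field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.voxel_resolution <= 0:
            raise ValueError("voxel resolution must be positive")
        self.origin = np.asarray(self.origin, float)
        self.occupancy = np.asarray(self.occupancy, bool)

    @property
    def voxel_count(self) -> int:
        return int(self.occupancy.sum())

    @property
    def volume_mm3(self) -> float:
        return self.voxel_count * self.voxel_resolution ** 3

    @property
    def is_empty(self) -> bool:
        return self.voxel_count == 0

    def same_grid(self, other: "VTA") -> bool:
        return (np.isclose(self.voxel_resolution, other.voxel_resolution)
                and self.occupancy.shape == other.occupancy.shape
                and np.allclose(self.origin, other.origin))

    def contains_points(self, points: np.ndarray) -> np.ndarray:
        """Membership test for (n, 3) query points in mm."""
        pts = np.asarray(points, float).reshape(-1, 3)
        if self.active_points is not None:
            if len(self.active_points) == 0:
                return np.zeros(len(pts), bool)
            if self._tree is None:
                self._tree = cKDTree(self.active_points)
            d, _ = self._tree.query(pts, k=1)
            return d <= self.stamp_radius
        idx = np.floor((pts - self.origin) / self.voxel_resolution).astype(int)
        ok = np.all((idx >= 0) & (idx < np.array(self.occupancy.shape)), axis=1)
        out = np.zeros(len(pts), bool)
        if ok.any():
            ii = idx[ok]
            out[ok] = self.occupancy[ii[:, 0], ii[:, 1], ii[:, 2]]
        return out

    def z_extent(self) -> tuple[float, float]:
        return (float(self.origin[2]),
                float(self.origin[2] + self.occupancy.shape[2] * self.voxel_resolution))

    def save_provenance(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"voxel_resolution": self.voxel_resolution,
                       "origin": self.origin.tolist(),
                       "shape": list(self.occupancy.shape),
                       "voxel_count": self.voxel_count,
                       "volume_mm3": self.volume_mm3,
                       **self.provenance}, fh, indent=2)


# ---------------------------------------------------------------------------
# activating function

def activating_function(node_potentials: np.ndarray) -> float:
    """Peak discrete second difference over interior nodes (volts).

    For a cathodic (negative) potential well this is positive at the axon
    node nearest the source; it is exactly linear in the potentials.
    """
    v = np.asarray(node_potentials, float)
    if v.ndim != 1 or v.size < 3:
        raise ValueError("an axon needs at least 3 node potentials")
    return float(np.max(v[:-2] - 2.0 * v[1:-1] + v[2:]))


def _sd2_along_axis(v: np.ndarray) -> np.ndarray:
    """Per-interior-node second differences along the last axis."""
    return v[..., :-2] - 2.0 * v[..., 1:-1] + v[..., 2:]


def _af_along_axis(v: np.ndarray) -> np.ndarray:
    """Vectorized peak second difference along the last axis."""
    return np.max(_sd2_along_axis(v), axis=-1)


# ---------------------------------------------------------------------------
# rasterization

def _voxel_grid(grid: AxonGridSpec, z_center: float, res: float):
    ext = grid.radial_extent + grid.grid_spacing
    vext = grid.vertical_extent + grid.grid_spacing
    origin = np.array([-ext, -ext, z_center - vext])
    n_xy = int(np.ceil(2 * ext / res))
    n_z = int(np.ceil(2 * vext / res))
    return origin, (n_xy, n_xy, n_z)


def _rasterize(points: np.ndarray, origin: np.ndarray, shape: tuple,
               res: float, stamp_radius: float) -> np.ndarray:
    occ = np.zeros(shape, bool)
    if len(points) == 0:
        return occ
    k = int(np.ceil(stamp_radius / res)) + 1
    offs = np.arange(-k, k + 1)
    off = np.stack(np.meshgrid(offs, offs, offs, indexing="ij"), -1).reshape(-1, 3)
    base = np.floor((points - origin) / res).astype(int)
    idx = base[:, None, :] + off[None, :, :]
    centers = origin + (idx + 0.5) * res
    mask = ((centers - points[:, None, :]) ** 2).sum(-1) <= stamp_radius ** 2
    idx = idx[mask]
    ok = np.all((idx >= 0) & (idx < np.array(shape)), axis=1)
    idx = idx[ok]
    occ[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    return occ


# ---------------------------------------------------------------------------
# axon lattice

def _lattice_nodes(grid: AxonGridSpec, z_center: float):
    """Axon centres (N, 3) and per-axon node positions (N, nodes, 3)."""
    ang = np.deg2rad(grid.plane_angles)
    rr = grid.radial_positions
    zz = grid.vertical_positions(z_center)
    A, R, Z = np.meshgrid(ang, rr, zz, indexing="ij")
    a, r, z = A.ravel(), R.ravel(), Z.ravel()
    centers = np.column_stack([r * np.cos(a), r * np.sin(a), z])
    dirs = np.column_stack([-np.sin(a), np.cos(a), np.zeros_like(a)])
    half = (grid.nodes_per_axon - 1) // 2
    s = (np.arange(grid.nodes_per_axon) - half) * grid.node_spacing
    nodes = centers[:, None, :] + s[None, :, None] * dirs[:, None, :]
    return centers, nodes


def _polar_nodes(grid: AxonGridSpec, z_center: float, r_step: float):
    """Dense polar axon centres: all 360 integer-degree directions x dense radii."""
    n_r = int(np.floor((grid.radial_extent - grid.inner_radial_margin) / r_step)) + 1
    rr = grid.inner_radial_margin + np.arange(n_r) * r_step
    ang = np.deg2rad(np.arange(360.0))
    return ang, rr


# ---------------------------------------------------------------------------
# simulator facade with per-electrode unit-field caches

class SteeringModel:
    """Cached simulator for one lead/tissue/lattice configuration.

    Precomputes, per electrode, the peak activating function produced by a
    1 mA cathodic setting ("unit AF") on both the axon lattice and a dense
    polar raster at the electrode-centre plane.  Every paradigm, amplitude and
    fractionalization then reduces to scaling and summing these unit tables
    (the activating function is linear in the source currents), which makes
    titration and full-grid runs cheap and exactly deterministic.
    """

    def __init__(self, geometry: LeadGeometry | None = None,
                 tissue: TissueModel | None = None,
                 grid: AxonGridSpec | None = None,
                 activation: ActivationModel | None = None,
                 voxel_resolution: float = 0.1,
                 n_per_axis: int = 4,
                 polar_r_step: float = 0.01,
                 level: int = 1):
        self.geometry = geometry or build_default_lead()
        self.tissue = tissue or TissueModel()
        self.grid = grid or AxonGridSpec()
        self.activation = activation
        self.voxel_resolution = voxel_resolution
        self.n_per_axis = n_per_axis
        self.polar_r_step = polar_r_step
        # electrode-centre plane of the first directional level by default
        dir_levels = [lv for lv in self.geometry.levels if lv.kind == "directional"]
        if not dir_levels:
            raise ValueError("geometry has no directional level")
        self.level = dir_levels[level - 1]
        self.z_center = self.level.z_center
        self._lat_centers, self._lat_nodes = _lattice_nodes(self.grid, self.z_center)
        self._polar_ang, self.polar_r = _polar_nodes(self.grid, self.z_center,
                                                     polar_r_step)
        self._unit_af_lat: dict[int, np.ndarray] = {}
        self._unit_af_pol: dict[int, np.ndarray] = {}

    # -- unit second-difference tables -----------------------------------
    # the caches hold per-node second-difference profiles (not their maxima):
    # simultaneous activation sums fields BEFORE the peak is taken, so
    # profiles must be mixed first and maximized after.

    def _unit_sources(self, electrode: int) -> SourceConfiguration:
        return make_sources(self.geometry, {electrode: -100.0}, 1.0,
                            n_per_axis=self.n_per_axis)

    def unit_sd2_lattice(self, electrode: int) -> np.ndarray:
        """(n_axons, nodes-2) second differences for 1 mA cathodic."""
        if electrode not in self._unit_af_lat:
            src = self._unit_sources(electrode)
            v = potential_at(self._lat_nodes, src, self.tissue)
            self._unit_af_lat[electrode] = _sd2_along_axis(v)
        return self._unit_af_lat[electrode]

    def unit_sd2_polar(self, electrode: int) -> np.ndarray:
        """(360, n_r, nodes-2) second differences at the centre plane."""
        if electrode not in self._unit_af_pol:
            src = self._unit_sources(electrode)
            ang, rr = self._polar_ang, self.polar_r
            half = (self.grid.nodes_per_axon - 1) // 2
            s = (np.arange(self.grid.nodes_per_axon) - half) * self.grid.node_spacing
            out = np.empty((ang.size, rr.size, self.grid.nodes_per_axon - 2))
            for i0 in range(0, ang.size, 45):  # chunk over angle to bound memory
                a = ang[i0:i0 + 45]
                ca, sa = np.cos(a), np.sin(a)
                cx = rr[None, :, None] * ca[:, None, None] \
                    - s[None, None, :] * sa[:, None, None]
                cy = rr[None, :, None] * sa[:, None, None] \
                    + s[None, None, :] * ca[:, None, None]
                cz = np.full_like(cx, self.z_center)
                pts = np.stack([cx, cy, cz], axis=-1)
                v = potential_at(pts, src, self.tissue)
                out[i0:i0 + 45] = _sd2_along_axis(v)
            self._unit_af_pol[electrode] = out
        return self._unit_af_pol[electrode]

    def unit_af_lattice(self, electrode: int) -> np.ndarray:
        """Peak AF per lattice axon for 1 mA cathodic on ``electrode``."""
        return np.max(self.unit_sd2_lattice(electrode), axis=-1)

    def unit_af_polar(self, electrode: int) -> np.ndarray:
        """(360, n_r) peak AF for 1 mA cathodic on ``electrode``."""
        return np.max(self.unit_sd2_polar(electrode), axis=-1)

    # -- calibration -----------------------------------------------------

    def calibrate(self, anchor_amplitude_mA: float = 1.6,
                  anchor_radius_mm: float = 3.0, electrode: int = 2) -> "SteeringModel":
        """Fix the AF threshold so a single-electrode setting at the anchor
        amplitude reaches the anchor radius along the electrode's centre ray."""
        if not (self.grid.inner_radial_margin < anchor_radius_mm
                < self.grid.radial_extent):
            raise ValueError("anchor radius outside axon-grid extent")
        row = self.unit_af_polar(electrode)[
            int(round(self.geometry.angular_center(electrode))) % 360]
        af_at_anchor = float(np.interp(anchor_radius_mm, self.polar_r, row))
        thr = anchor_amplitude_mA * af_at_anchor
        if thr <= 0:
            raise ValueError("anchor radius unreachable at any finite threshold")
        # the boundary must actually sit at the anchor (AF monotone there)
        reached = float(self.polar_r[anchor_amplitude_mA * row >= thr].max())
        if abs(reached - anchor_radius_mm) > max(self.polar_r_step, 1e-6):
            raise ValueError("calibration failed: non-monotone AF at anchor radius")
        self.activation = ActivationModel(
            af_threshold=thr,
            calibration_anchor={"amplitude_mA": anchor_amplitude_mA,
                                "radius_mm": anchor_radius_mm,
                                "electrode": electrode})
        return self

    def _require_calibrated(self) -> float:
        if self.activation is None:
            raise RuntimeError("model is not calibrated; call calibrate() first")
        return self.activation.af_threshold

    # -- polar occupancy (dense, used by titration) ----------------------

    def _magnitudes(self, distribution: Mapping[int, float],
                    total_amplitude_mA: float) -> dict[int, float]:
        mags = [abs(v) for v in distribution.values()]
        if abs(sum(mags) - 100.0) > 1e-9:
            raise ValueError("fraction magnitudes must sum to 100%")
        return {int(e): abs(p) / 100.0 * total_amplitude_mA
                for e, p in distribution.items()}

    def polar_occupancy(self, distribution: Mapping[int, float],
                        total_amplitude_mA: float,
                        paradigm: str = "micc") -> np.ndarray:
        """(360, n_r) boolean occupancy of the centre-plane cross-section."""
        thr = self._require_calibrated()
        amps = self._magnitudes(distribution, total_amplitude_mA)
        if paradigm == "micc":
            sd2 = np.zeros_like(self.unit_sd2_polar(next(iter(amps))))
            for e, a in amps.items():
                if a > 0:
                    sd2 += a * self.unit_sd2_polar(e)
            return np.max(sd2, axis=-1) >= thr
        if paradigm == "interleaving":
            occ = np.zeros((360, self.polar_r.size), bool)
            for e, a in amps.items():
                if a > 0:
                    occ |= a * self.unit_af_polar(e) >= thr
            return occ
        raise ValueError(f"unknown paradigm {paradigm!r}")

    def polar_bisector_radius(self, occ: np.ndarray) -> tuple[float, float]:
        """(bisector angle deg, radius mm at that angle); (nan, 0) if empty."""
        if not occ.any():
            return float("nan"), 0.0
        ang = equal_area_angle(occ, self.polar_r, self.polar_r_step)
        return ang, radius_at_angle(occ, self.polar_r, ang)

    # -- titration -------------------------------------------------------

    def titrate(self, distribution: Mapping[int, float], target_radius_mm: float,
                paradigm: str = "micc", amp_tol_mA: float = 0.01,
                radius_tol_mm: float = 0.025, max_iter: int = 60,
                control: str = "bisector") -> float:
        """Smallest total amplitude whose VTA radius reaches the target.

        ``control='bisector'`` (default) measures the radius along the
        equal-area bisector direction; ``control='max'`` measures the overall
        maximum radius over all directions.
        """
        if not (self.grid.inner_radial_margin < target_radius_mm
                < self.grid.radial_extent):
            raise ValueError("target radius outside axon-grid extent")
        if control not in ("bisector", "max"):
            raise ValueError("control must be 'bisector' or 'max'")

        def measure(a: float) -> float:
            occ = self.polar_occupancy(distribution, a, paradigm)
            if control == "max":
                cols = occ.any(axis=0)
                return float(self.polar_r[cols].max()) if cols.any() else 0.0
            return self.polar_bisector_radius(occ)[1]

        lo, hi = 0.0, 1.0
        while measure(hi) < target_radius_mm:
            hi *= 2.0
            if hi > 512.0:
                raise ValueError("target radius not bracketable by amplitude")
        # bisect on the crossing amplitude; hi always reaches the target, so
        # the final hi is the smallest amplitude found that does
        for _ in range(max_iter):
            if hi - lo < amp_tol_mA:
                break
            mid = 0.5 * (lo + hi)
            if measure(mid) < target_radius_mm:
                lo = mid
            else:
                hi = mid
        achieved = measure(hi)
        if abs(achieved - target_radius_mm) > radius_tol_mm + self.polar_r_step:
            raise ValueError(
                f"titration reached radius {achieved:.3f} mm for target "
                f"{target_radius_mm:.3f} mm (outside tolerance)")
        return hi

    # -- voxel VTAs ------------------------------------------------------

    def _vta_from_active(self, active: np.ndarray, provenance: dict) -> VTA:
        pts = self._lat_centers[active]
        origin, shape = _voxel_grid(self.grid, self.z_center, self.voxel_resolution)
        stamp = self.grid.grid_spacing / 2.0
        occ = _rasterize(pts, origin, shape, self.voxel_resolution, stamp)
        return VTA(self.voxel_resolution, origin, occ, active_points=pts,
                   stamp_radius=stamp, provenance=provenance)

    def build_micc_vta(self, distribution: Mapping[int, float],
                       total_amplitude_mA: float,
                       target_radius: float | None = None) -> VTA:
        """Simultaneous activation: per-electrode fields sum before thresholding."""
        thr = self._require_calibrated()
        amps = self._magnitudes(distribution, total_amplitude_mA)
        sd2 = np.zeros((self._lat_centers.shape[0], self.grid.nodes_per_axon - 2))
        for e, a in amps.items():
            if a > 0:
                sd2 += a * self.unit_sd2_lattice(e)
        af = np.max(sd2, axis=-1)
        return self._vta_from_active(af >= thr, {
            "paradigm": "micc", "distribution": dict(distribution),
            "total_amplitude_mA": total_amplitude_mA,
            "target_radius_mm": target_radius,
            **_surrogate_note()})

    def build_single_electrode_vta(self, electrode: int, amplitude_mA: float,
                                   provenance: dict | None = None) -> VTA:
        thr = self._require_calibrated()
        af = amplitude_mA * self.unit_af_lattice(electrode)
        prov = provenance or {}
        return self._vta_from_active(af >= thr, {
            "paradigm": "single", "electrode": electrode,
            "amplitude_mA": amplitude_mA, **prov, **_surrogate_note()})

    def build_interleaving_vtas(self, distribution: Mapping[int, float],
                                total_amplitude_mA: float,
                                target_radius: float | None = None
                                ) -> dict[str, VTA | None]:
        """Alternate activation: one electrode active per VTA, no field summation.

        ``vta2`` (the weaker electrode's VTA) is ``None`` when no axon crosses
        threshold at its fractional amplitude.
        """
        amps = self._magnitudes(distribution, total_amplitude_mA)
        nonzero = [(e, a) for e, a in amps.items()]
        if len(nonzero) != 2:
            raise ValueError("interleaving requires a two-electrode fractionalization")
        nonzero.sort(key=lambda t: -t[1])  # dominant first
        out: dict[str, VTA | None] = {}
        for name, (e, a) in zip(("vta1", "vta2"), nonzero):
            if a <= 0:
                out[name] = None
                continue
            v = self.build_single_electrode_vta(e, a, {
                "paradigm": "interleaving", "role": name,
                "distribution": dict(distribution),
                "total_amplitude_mA": total_amplitude_mA,
                "target_radius_mm": target_radius})
            out[name] = None if v.is_empty else v
        return out


def _surrogate_note() -> dict:
    return {"field_model": "point-source superposition, homogeneous medium",
            "activation_model": "calibrated activating-function threshold",
            "encapsulation_in_field": False}


# ---------------------------------------------------------------------------
# module-level operations (thin wrappers over SteeringModel)

def calibrate_threshold(geometry: LeadGeometry | None = None,
                        tissue: TissueModel | None = None,
                        grid: AxonGridSpec | None = None,
                        anchor: Mapping[str, float] | None = None) -> ActivationModel:
    """Calibrate the AF threshold at a (amplitude, radius) single-electrode anchor."""
    anchor = dict(anchor or {})
    model = SteeringModel(geometry, tissue, grid)
    model.calibrate(anchor.get("amplitude_mA", 1.6), anchor.get("radius_mm", 3.0),
                    int(anchor.get("electrode", 2)))
    assert model.activation is not None
    return model.activation


def build_vta(sources: SourceConfiguration, model: ActivationModel,
              grid: AxonGridSpec | None = None,
              voxel_resolution: float = 0.1,
              tissue: TissueModel | None = None) -> VTA:
    """Build a VTA for an arbitrary simultaneous source configuration.

    Generic path: evaluates the field at every lattice axon directly (no
    caching); used for one-off builds and as the reference for the cached
    ``SteeringModel`` routes.
    """
    grid = grid or AxonGridSpec()
    tissue = tissue or TissueModel()
    if sources.z_center is None:
        raise ValueError("source configuration has no active electrode / z_center")
    centers, nodes = _lattice_nodes(grid, sources.z_center)
    if sources.positions.shape[0] == 0 or np.all(sources.currents_mA == 0):
        active = np.zeros(centers.shape[0], bool)
    else:
        af = _af_along_axis(potential_at(nodes, sources, tissue))
        active = af >= model.af_threshold
    origin, shape = _voxel_grid(grid, sources.z_center, voxel_resolution)
    stamp = grid.grid_spacing / 2.0
    occ = _rasterize(centers[active], origin, shape, voxel_resolution, stamp)
    return VTA(voxel_resolution, origin, occ, active_points=centers[active],
               stamp_radius=stamp,
               provenance={"paradigm": "micc",
                           "electrode_amplitudes_mA": dict(sources.electrode_amplitudes_mA),
                           **_surrogate_note()})


def titrate_amplitude(distribution: Mapping[int, float], target_radius: float,
                      paradigm: str = "micc",
                      model: ActivationModel | None = None,
                      grid: AxonGridSpec | None = None,
                      geometry: LeadGeometry | None = None,
                      tissue: TissueModel | None = None) -> float:
    """Bisect the total amplitude until the VTA bisector radius hits the target."""
    sm = SteeringModel(geometry, tissue, grid, activation=model)
    if sm.activation is None:
        sm.calibrate()
    return sm.titrate(distribution, target_radius, paradigm)


def build_interleaving_vtas(distribution: Mapping[int, float],
                            total_amplitude: float,
                            model: ActivationModel | None = None,
                            grid: AxonGridSpec | None = None,
                            geometry: LeadGeometry | None = None,
                            tissue: TissueModel | None = None
                            ) -> dict[str, VTA | None]:
    sm = SteeringModel(geometry, tissue, grid, activation=model)
    if sm.activation is None:
        sm.calibrate()
    return sm.build_interleaving_vtas(distribution, total_amplitude)


def vta_union(a: VTA, b: VTA) -> VTA:
    if not a.same_grid(b):
        raise ValueError("VTAs must share resolution, origin and shape")
    pts = None
    if a.active_points is not None and b.active_points is not None:
        pts = np.vstack([a.active_points, b.active_points])
    return VTA(a.voxel_resolution, a.origin, a.occupancy | b.occupancy,
               active_points=pts, stamp_radius=a.stamp_radius,
               provenance={"op": "union",
                           "parents": [a.provenance.get("paradigm"),
                                       b.provenance.get("paradigm")]})


def vta_intersection(a: VTA, b: VTA) -> VTA:
    if not a.same_grid(b):
        raise ValueError("VTAs must share resolution, origin and shape")
    # the sphere-union representation does not compose under intersection
    return VTA(a.voxel_resolution, a.origin, a.occupancy & b.occupancy,
               active_points=None, stamp_radius=a.stamp_radius,
               provenance={"op": "intersection",
                           "parents": [a.provenance.get("paradigm"),
                                       b.provenance.get("paradigm")]})


def scan_radius_1d(distribution: Mapping[int, float], total_amplitude: float,
                   model: ActivationModel, angle_deg: float,
                   grid: AxonGridSpec | None = None,
                   geometry: LeadGeometry | None = None,
                   tissue: TissueModel | None = None,
                   r_step: float = 0.01, paradigm: str = "micc",
                   n_per_axis: int = 4) -> float:
    """Independent dense 1-D threshold scan along one ray (brute force).

    Evaluates the field and peak AF directly (no caches) for axons centred
    along the ray at ``angle_deg`` in the electrode-centre plane and returns
    the largest radius whose AF crosses threshold (0 if none).
    """
    grid = grid or AxonGridSpec()
    geometry = geometry or build_default_lead()
    tissue = tissue or TissueModel()
    z_c = geometry.level_of(next(iter(distribution))).z_center
    n_r = int(np.floor((grid.radial_extent - grid.inner_radial_margin) / r_step)) + 1
    rr = grid.inner_radial_margin + np.arange(n_r) * r_step
    a = np.deg2rad(angle_deg)
    half = (grid.nodes_per_axon - 1) // 2
    s = (np.arange(grid.nodes_per_axon) - half) * grid.node_spacing
    cx = rr[:, None] * np.cos(a) - s[None, :] * np.sin(a)
    cy = rr[:, None] * np.sin(a) + s[None, :] * np.cos(a)
    pts = np.stack([cx, cy, np.full_like(cx, z_c)], axis=-1)

    mags = {int(e): abs(p) / 100.0 * total_amplitude for e, p in distribution.items()}
    if paradigm == "micc":
        src = make_sources(geometry, distribution, total_amplitude, n_per_axis)
        af = _af_along_axis(potential_at(pts, src, tissue))
        hit = af >= model.af_threshold
    elif paradigm == "interleaving":
        hit = np.zeros(rr.size, bool)
        for e, amp in mags.items():
            if amp > 0:
                src = make_sources(geometry, {e: -100.0}, amp, n_per_axis)
                af = _af_along_axis(potential_at(pts, src, tissue))
                hit |= af >= model.af_threshold
    else:
        raise ValueError(f"unknown paradigm {paradigm!r}")
    if not hit.any():
        return 0.0
    return float(rr[hit].max())
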