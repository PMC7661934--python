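"""VTA engine: activating function, calibration, titration, set algebra,
paradigm-defining symmetries."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial import cKDTree

from dbssteer import (ActivationModel, AxonGridSpec, SteeringModel, VTA,
                      activating_function, build_default_lead, build_vta,
                      make_sources, scan_radius_1d, vta_intersection,
                      vta_union)

TABLE5_SINGLE_AMPS = [0.6, 0.8, 1.0, 1.3, 1.6, 2.0, 2.4, 3.0, 3.5]


def _reflect_about(points: np.ndarray, axis_deg: float) -> np.ndarray:
    """Reflect (n, 3) points about the vertical half-plane at ``axis_deg``."""
    a = np.deg2rad(2.0 * axis_deg)
    R = np.array([[np.cos(a), np.sin(a)], [np.sin(a), -np.cos(a)]])
    out = points.copy()
    out[:, :2] = points[:, :2] @ R.T
    return out


def _rotate(points: np.ndarray, angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    out = points.copy()
    out[:, :2] = points[:, :2] @ R.T
    return out


def _point_sets_equal(a: np.ndarray, b: np.ndarray, tol: float = 1e-9) -> bool:
    if len(a) != len(b):
        return False
    if len(a) == 0:
        return True
    d1, _ = cKDTree(b).query(a, k=1)
    d2, _ = cKDTree(a).query(b, k=1)
    return d1.max() < tol and d2.max() < tol


class TestActivatingFunction:
    def test_triangle_potential(self):
        assert activating_function([0.0, -1.0, 0.0]) == pytest.approx(2.0)

    @given(a=st.floats(-5, 5), b=st.floats(-5, 5))
    def test_linear_ramp_gives_zero(self, a, b):
        v = a * np.arange(9) + b
        assert activating_function(v) == pytest.approx(0.0, abs=1e-9)

    def test_linearity_in_potentials(self):
        v = np.array([-0.1, -0.5, -1.2, -0.4, -0.05])
        assert activating_function(2 * v) == pytest.approx(
            2 * activating_function(v), rel=1e-12)

    def test_too_few_nodes(self):
        with pytest.raises(ValueError):
            activating_function([0.0, -1.0])


class TestCalibration:
    def test_anchor_radius_recovered_by_dense_scan(self, steering_model):
        """The 1.6 mA single-electrode setting reaches 3.00 mm along its own
        centre ray (brute-force scan, independent of the cached tables)."""
        r = scan_radius_1d({2: -100.0}, 1.6, steering_model.activation, 0.0)
        assert r == pytest.approx(3.0, abs=0.011)

    def test_voxel_vta_radius_near_anchor(self, steering_model):
        from dbssteer import cross_section, vta_radius
        v = steering_model.build_micc_vta({2: -100.0}, 1.6)
        cs = cross_section(v, z_plane=steering_model.z_center)
        # voxel route quantizes at half the 0.5 mm lattice spacing
        assert vta_radius(cs, 0.0) == pytest.approx(3.0, abs=0.3)

    def test_radius_monotone_over_single_electrode_amplitudes(self, steering_model):
        radii = [scan_radius_1d({2: -100.0}, a, steering_model.activation, 0.0)
                 for a in TABLE5_SINGLE_AMPS]
        assert all(b >= a for a, b in zip(radii, radii[1:]))

    def test_infinite_threshold_empty_vta(self):
        g = build_default_lead()
        src = make_sources(g, {2: -100.0}, 3.5)
        v = build_vta(src, ActivationModel(af_threshold=1e9))
        assert v.is_empty

    def test_anchor_outside_grid_rejected(self):
        m = SteeringModel(grid=AxonGridSpec(radial_extent=4.0))
        with pytest.raises(ValueError, match="extent"):
            m.calibrate(anchor_radius_mm=5.0)

    def test_uncalibrated_model_refuses_to_build(self):
        m = SteeringModel()
        with pytest.raises(RuntimeError, match="calibrat"):
            m.build_micc_vta({2: -100.0}, 1.0)


class TestBuildVta:
    def test_zero_amplitude_empty(self, steering_model):
        v = steering_model.build_micc_vta({2: -100.0}, 0.0)
        assert v.is_empty and v.volume_mm3 == 0.0

    def test_equal_split_mirror_symmetric_about_60(self, steering_model):
        v = steering_model.build_micc_vta({2: -50.0, 3: -50.0}, 2.0)
        assert not v.is_empty
        assert _point_sets_equal(_reflect_about(v.active_points, 60.0),
                                 v.active_points)

    def test_swapped_fractionalizations_mirror(self, steering_model):
        """VTA(-70/-30) is VTA(-30/-70) reflected about the 60-deg half-plane."""
        a = steering_model.build_micc_vta({2: -70.0, 3: -30.0}, 1.8)
        b = steering_model.build_micc_vta({2: -30.0, 3: -70.0}, 1.8)
        assert _point_sets_equal(_reflect_about(a.active_points, 60.0),
                                 b.active_points)

    def test_monotone_growth_in_amplitude(self, steering_model):
        lo = steering_model.build_micc_vta({2: -70.0, 3: -30.0}, 1.2)
        hi = steering_model.build_micc_vta({2: -70.0, 3: -30.0}, 2.0)
        assert np.all(lo.occupancy <= hi.occupancy)

    def test_cached_route_matches_generic_build(self, steering_model):
        """SteeringModel's cached unit-field route reproduces the direct
        field-evaluation route exactly."""
        dist, amp = {2: -60.0, 3: -40.0}, 1.5
        src = make_sources(steering_model.geometry, dist, amp)
        direct = build_vta(src, steering_model.activation, steering_model.grid,
                           tissue=steering_model.tissue)
        cached = steering_model.build_micc_vta(dist, amp)
        assert _point_sets_equal(direct.active_points, cached.active_points)

    def test_voxel_radius_agrees_with_1d_scan(self, steering_model):
        """Metric radius from the voxel VTA matches a dense 1-D threshold scan
        along the same ray, to within the lattice resolution."""
        from dbssteer import cross_section, vta_radius
        v = steering_model.build_micc_vta({2: -100.0}, 2.4)
        cs = cross_section(v, z_plane=steering_model.z_center)
        dense = scan_radius_1d({2: -100.0}, 2.4, steering_model.activation, 0.0)
        half_spacing = steering_model.grid.grid_spacing / 2.0
        assert abs(vta_radius(cs, 0.0) - dense) <= half_spacing + 0.05


class TestInterleaving:
    def test_equal_split_vtas_are_rotated_copies(self, steering_model):
        vtas = steering_model.build_interleaving_vtas({2: -50.0, 3: -50.0}, 3.0)
        v1, v2 = vtas["vta1"], vtas["vta2"]
        assert v1 is not None and v2 is not None
        assert _point_sets_equal(_rotate(v1.active_points, 120.0),
                                 v2.active_points)

    def test_zero_weak_electrode_vta2_absent(self, steering_model):
        vtas = steering_model.build_interleaving_vtas({2: -100.0, 3: 0.0}, 2.0)
        assert vtas["vta1"] is not None
        assert vtas["vta2"] is None

    def test_subthreshold_weak_electrode_vta2_absent(self, steering_model):
        # at a small total amplitude the 10% electrode's field alone cannot
        # activate even the innermost sampled axons
        vtas = steering_model.build_interleaving_vtas({2: -90.0, 3: -10.0}, 0.5)
        assert vtas["vta2"] is None

    def test_union_and_intersection_bracket_components(self, steering_model):
        vtas = steering_model.build_interleaving_vtas({2: -60.0, 3: -40.0}, 3.0)
        v1, v2 = vtas["vta1"], vtas["vta2"]
        assert v2 is not None
        u = vta_union(v1, v2)
        i = vta_intersection(v1, v2)
        assert np.all(i.occupancy <= v1.occupancy)
        assert np.all(i.occupancy <= v2.occupancy)
        assert np.all(v1.occupancy <= u.occupancy)
        assert np.all(v2.occupancy <= u.occupancy)

    def test_requires_two_electrodes(self, steering_model):
        with pytest.raises(ValueError, match="two-electrode"):
            steering_model.build_interleaving_vtas({2: -100.0}, 2.0)


def _random_vta(rng, shape=(6, 6, 6), p=0.3) -> VTA:
    occ = rng.random(shape) < p
    return VTA(0.5, np.zeros(3), occ)


class TestSetAlgebra:
    def test_idempotence(self, rng):
        a = _random_vta(rng)
        assert np.array_equal(vta_union(a, a).occupancy, a.occupancy)
        assert np.array_equal(vta_intersection(a, a).occupancy, a.occupancy)

    def test_disjoint_intersection_empty(self):
        occ_a = np.zeros((4, 4, 4), bool)
        occ_b = np.zeros((4, 4, 4), bool)
        occ_a[0, 0, 0] = True
        occ_b[3, 3, 3] = True
        a = VTA(0.5, np.zeros(3), occ_a)
        b = VTA(0.5, np.zeros(3), occ_b)
        assert vta_intersection(a, b).is_empty

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_inclusion_exclusion(self, seed):
        """|A u B| + |A n B| = |A| + |B| against brute-force set enumeration."""
        rng = np.random.default_rng(seed)
        a, b = _random_vta(rng), _random_vta(rng)
        lhs = vta_union(a, b).voxel_count + vta_intersection(a, b).voxel_count
        # oracle: enumerate voxel index sets explicitly
        sa = set(map(tuple, np.argwhere(a.occupancy)))
        sb = set(map(tuple, np.argwhere(b.occupancy)))
        assert lhs == len(sa) + len(sb)
        assert vta_union(a, b).voxel_count == len(sa | sb)
        assert vta_intersection(a, b).voxel_count == len(sa & sb)

    def test_mismatched_grids_rejected(self, rng):
        a = _random_vta(rng)
        b = VTA(0.4, np.zeros(3), np.zeros((6, 6, 6), bool))
        with pytest.raises(ValueError, match="share"):
            vta_union(a, b)
        c = VTA(0.5, np.array([1.0, 0.0, 0.0]), np.zeros((6, 6, 6), bool))
        with pytest.raises(ValueError, match="share"):
            vta_intersection(a, c)


class TestTitration:
    def test_single_electrode_anchor_amplitude(self, steering_model):
        a = steering_model.titrate({2: -100.0}, 3.0, "micc")
        assert a == pytest.approx(1.6, abs=0.02)

    @pytest.mark.parametrize("dist,paradigm", [
        ({2: -70.0, 3: -30.0}, "micc"),
        ({2: -50.0, 3: -50.0}, "interleaving"),
    ])
    def test_achieved_radius_within_tolerance(self, steering_model, dist, paradigm):
        target = 2.75
        a = steering_model.titrate(dist, target, paradigm)
        occ = steering_model.polar_occupancy(dist, a, paradigm)
        _, r = steering_model.polar_bisector_radius(occ)
        assert abs(r - target) <= 0.025 + steering_model.polar_r_step

    def test_amplitude_monotone_in_target_radius(self, steering_model):
        amps = [steering_model.titrate({2: -70.0, 3: -30.0}, r, "micc")
                for r in (2.0, 2.5, 3.0, 3.5, 4.0)]
        assert all(b >= a - 1e-9 for a, b in zip(amps, amps[1:]))

    def test_matches_brute_force_amplitude_sweep(self, steering_model):
        """Bisection finds the same crossing amplitude as an exhaustive sweep."""
        dist, target = {2: -60.0, 3: -40.0}, 3.0

        def radius(a):
            occ = steering_model.polar_occupancy(dist, a, "micc")
            return steering_model.polar_bisector_radius(occ)[1]

        sweep = np.arange(0.05, 4.0, 0.05)
        crossing = next(a for a in sweep if radius(a) >= target - 0.025)
        titrated = steering_model.titrate(dist, target, "micc")
        assert abs(titrated - crossing) <= 0.05 + 0.01

    def test_unreachable_target_errors(self, steering_model):
        with pytest.raises(ValueError, match="extent"):
            steering_model.titrate({2: -100.0}, 7.5, "micc")

    def test_max_control_needs_no_more_amplitude(self, steering_model):
        """Controlling the overall max radius titrates at most the amplitude
        of the bisector-radius control (the max radius is never smaller)."""
        dist, target = {2: -80.0, 3: -20.0}, 3.0
        a_bis = steering_model.titrate(dist, target, "interleaving")
        a_max = steering_model.titrate(dist, target, "interleaving",
                                       control="max")
        assert a_max <= a_bis + 0.01
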