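"""Steering metrics: equal-area bisector, radius, deviation, volume, overlap."""

import numpy as np
import pytest

from dbssteer import (VTA, cross_section, equal_area_bisector,
                      expected_rotation_angle, overlap_percent,
                      rotation_deviation, vta_radius, vta_volume)
from dbssteer.metrics import CrossSection, rotated_cross_section

N_R = 60
R_STEP = 0.05
R_CENTERS = (np.arange(N_R) + 0.5) * R_STEP


def _sector(start_deg: int, stop_deg: int, r_max: float = 2.5) -> CrossSection:
    occ = np.zeros((360, N_R), bool)
    rows = np.arange(start_deg, stop_deg) % 360
    occ[rows[:, None], np.where(R_CENTERS < r_max)[0][None, :]] = True
    return CrossSection(0.0, occ, R_CENTERS, R_STEP)


def _random_blob(seed: int) -> CrossSection:
    rng = np.random.default_rng(seed)
    # union of a few random sectors with random radial extents
    occ = np.zeros((360, N_R), bool)
    for _ in range(rng.integers(2, 5)):
        a0 = int(rng.integers(0, 360))
        width = int(rng.integers(20, 120))
        rmax = rng.uniform(0.8, 2.8)
        rows = np.arange(a0, a0 + width) % 360
        occ[rows[:, None], np.where(R_CENTERS < rmax)[0][None, :]] = True
    if not occ.any():
        occ[0, :10] = True
    return CrossSection(0.0, occ, R_CENTERS, R_STEP)


class TestEqualAreaBisector:
    def test_half_disc(self):
        assert equal_area_bisector(_sector(0, 180)) == pytest.approx(90.0)

    def test_symmetric_sector(self):
        assert equal_area_bisector(_sector(20, 100)) == pytest.approx(60.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_global_minimum_against_exhaustive_sweep(self, seed):
        """The returned line achieves the global minimum |A_left - A_right|
        over all 180 one-degree candidates (independent brute-force sweep)."""
        cs = _random_blob(seed)
        w = cs.r_centers * cs.radial_step * np.pi / 180.0
        a = cs.occupancy @ w
        best = min(
            abs(sum(a[(theta + k) % 360] for k in range(180)) * 2 - a.sum())
            for theta in range(180))
        theta_star = int(equal_area_bisector(cs)) % 180
        got = abs(sum(a[(theta_star + k) % 360] for k in range(180)) * 2
                  - a.sum())
        assert got == pytest.approx(best, abs=1e-12)

    @pytest.mark.parametrize("delta", [30, 90, 123, 270])
    def test_equivariance_under_rotation(self, delta):
        cs = _random_blob(3)
        base = equal_area_bisector(cs)
        rot = equal_area_bisector(rotated_cross_section(cs, delta))
        d = abs((rot - base - delta + 180.0) % 360.0 - 180.0)
        assert d <= 1.0

    def test_empty_errors(self):
        cs = CrossSection(0.0, np.zeros((360, N_R), bool), R_CENTERS, R_STEP)
        with pytest.raises(ValueError, match="empty"):
            equal_area_bisector(cs)


class TestVtaRadius:
    def test_disc_radius(self):
        cs = _sector(0, 360, r_max=2.0)
        assert vta_radius(cs, 123.0) == pytest.approx(2.0, abs=R_STEP)

    def test_empty_direction_is_zero(self):
        cs = _sector(10, 20)
        assert vta_radius(cs, 200.0) == 0.0

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_ray_marching_oracle(self, seed):
        cs = _random_blob(seed)
        for ang in (0, 45, 133, 301):
            expected = 0.0
            for j in range(N_R - 1, -1, -1):  # brute-force walk inward
                if cs.occupancy[ang, j]:
                    expected = cs.r_centers[j]
                    break
            assert vta_radius(cs, float(ang)) == pytest.approx(expected)


class TestExpectedRotation:
    @pytest.mark.parametrize("dist,angle", [
        ({2: -50.0, 3: -50.0}, 60.0),
        ({2: -60.0, 3: -40.0}, 48.0),
        ({2: -70.0, 3: -30.0}, 36.0),
        ({2: -80.0, 3: -20.0}, 24.0),
        ({2: -90.0, 3: -10.0}, 12.0),
        ({2: -100.0, 3: 0.0}, 0.0),
    ])
    def test_linear_proportion(self, dist, angle):
        assert expected_rotation_angle(dist) == pytest.approx(angle)

    def test_rejects_three_electrodes(self):
        with pytest.raises(ValueError):
            expected_rotation_angle({2: -34.0, 3: -33.0, 4: -33.0})


class TestRotationDeviation:
    @pytest.mark.parametrize("m,e,d", [(60, 60, 0), (36, 29, 7), (359, 1, 2)])
    def test_wraparound_difference(self, m, e, d):
        assert rotation_deviation(m, e) == pytest.approx(d)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            rotation_deviation(float("nan"), 0.0)


class TestVolumeAndOverlap:
    def test_empty_volume(self):
        v = VTA(0.5, np.zeros(3), np.zeros((4, 4, 4), bool))
        assert vta_volume(v) == 0.0

    def test_eight_voxels_at_half_mm(self):
        occ = np.zeros((4, 4, 4), bool)
        occ[:2, :2, :2] = True
        assert vta_volume(VTA(0.5, np.zeros(3), occ)) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [11, 12])
    def test_volume_matches_count_oracle(self, seed):
        rng = np.random.default_rng(seed)
        occ = rng.random((5, 5, 5)) < 0.4
        v = VTA(0.2, np.zeros(3), occ)
        assert vta_volume(v) == pytest.approx(
            len(np.argwhere(occ)) * 0.2 ** 3)

    def test_overlap_identical_and_disjoint(self):
        occ_a = np.zeros((4, 4, 4), bool)
        occ_a[:2] = True
        a = VTA(0.5, np.zeros(3), occ_a)
        assert overlap_percent(a, a) == pytest.approx(100.0)
        occ_b = np.zeros((4, 4, 4), bool)
        occ_b[3] = True
        b = VTA(0.5, np.zeros(3), occ_b)
        assert overlap_percent(a, b) == 0.0

    def test_overlap_quarter_subset(self):
        occ_b = np.zeros((4, 4, 4), bool)
        occ_b[:2, :2] = True  # 16 voxels
        occ_a = np.zeros((4, 4, 4), bool)
        occ_a[:1, :1] = True  # 4 voxels, subset of b
        a, b = VTA(0.5, np.zeros(3), occ_a), VTA(0.5, np.zeros(3), occ_b)
        assert overlap_percent(a, b) == pytest.approx(25.0)

    def test_overlap_empty_reference_errors(self):
        a = VTA(0.5, np.zeros(3), np.ones((2, 2, 2), bool))
        b = VTA(0.5, np.zeros(3), np.zeros((2, 2, 2), bool))
        with pytest.raises(ValueError, match="empty"):
            overlap_percent(a, b)


class TestCrossSection:
    def test_empty_vta_gives_flagged_empty_section(self):
        v = VTA(0.5, np.array([-2.0, -2.0, -2.0]), np.zeros((8, 8, 8), bool))
        cs = cross_section(v, z_plane=0.0)
        assert cs.is_empty and cs.meta["empty"]

    def test_z_plane_outside_extent_rejected(self):
        v = VTA(0.5, np.zeros(3), np.ones((4, 4, 4), bool))
        with pytest.raises(ValueError, match="extent"):
            cross_section(v, z_plane=5.0)

    def test_full_disc_occupies_all_radial_samples(self):
        # voxel cube centred on the axis: inner disc fully occupied
        n = 16
        occ = np.ones((n, n, n), bool)
        v = VTA(0.5, np.array([-4.0, -4.0, -4.0]), occ)
        cs = cross_section(v, z_plane=0.0)
        inside = cs.r_centers < 3.5  # strictly inside the cube face
        assert cs.occupancy[:, inside].all(axis=1).sum() > 300

    @pytest.mark.parametrize("seed", [21, 22, 23])
    def test_polar_area_matches_voxel_slice_area(self, seed):
        """Occupied polar area equals the voxel-slice area within ~2 voxel
        areas (direct voxel-count oracle) for random voxel blobs."""
        rng = np.random.default_rng(seed)
        n, res = 12, 0.5
        occ = np.zeros((n, n, n), bool)
        # random connected-ish blob in one z-slab
        k = n // 2
        blob = rng.random((n, n)) < 0.35
        occ[:, :, k] = blob
        v = VTA(res, np.array([-3.0, -3.0, -3.0]), occ)
        z_mid = -3.0 + (k + 0.5) * res
        cs = cross_section(v, z_plane=z_mid)
        voxel_area = blob.sum() * res ** 2
        assert cs.area_mm2() == pytest.approx(voxel_area, abs=2.0 * res ** 2)
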