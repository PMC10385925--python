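import numpy as np
import pytest
from scipy.spatial.distance import cdist

from adrenoct import LabelMask, PhantomSpec, compute_volume, make_phantom
from adrenoct.morphometry import (
    GlandFrame,
    aortic_dorsoventral_diameter,
    craniocaudal_length,
    gland_frame_from_mask,
    height_width_at,
    locate_poles_and_isthmus,
    reorient_to_gland_frame,
)


def _box_mask(extent_mm, spacing):
    shape = tuple(int(round(e / s)) for e, s in zip(extent_mm, spacing))
    return LabelMask(np.ones(shape, dtype=int), spacing, ("CC", "DV", "ML"))


class TestCraniocaudalLength:
    def test_box_diagonal_matches_brute_force(self):
        # 30 x 10 x 5 mm box at 1 mm: farthest voxel-centre pair, verified
        # against an exhaustive all-pairs scan
        mask = _box_mask((30, 10, 5), (1.0, 1.0, 1.0))
        length, (p, q) = craniocaudal_length(mask)
        pts = np.argwhere(mask.occupancy).astype(float)
        brute = cdist(pts, pts).max()
        assert length == pytest.approx(brute, rel=1e-12)
        # centre-to-centre diagonal of a 30x10x5 box digitised at 1 mm
        assert length == pytest.approx(np.sqrt(29**2 + 9**2 + 4**2), rel=1e-12)

    def test_ellipsoid_major_axis(self, iso_ellipsoid):
        _, mask, truth = iso_ellipsoid
        length, _ = craniocaudal_length(mask)
        voxel_diag = np.linalg.norm(mask.spacing)
        assert abs(length - truth["length_mm"]) <= voxel_diag

    def test_rotation_invariance(self):
        base = PhantomSpec(shape="ellipsoid", semi_axes_mm=(15, 5, 4),
                           spacing=(0.4, 0.4, 0.4))
        rot = PhantomSpec(shape="ellipsoid", semi_axes_mm=(15, 5, 4),
                          spacing=(0.4, 0.4, 0.4), pose_deg=(0, 30, 0))
        l0 = craniocaudal_length(make_phantom(base)[1])[0]
        l1 = craniocaudal_length(make_phantom(rot)[1])[0]
        # 2% plus one voxel diagonal of digitisation slack
        assert abs(l1 - l0) <= 0.02 * l0 + np.linalg.norm((0.4, 0.4, 0.4))

    def test_sphere_l_h_w_agree(self, iso_sphere_r5):
        _, mask, _ = iso_sphere_r5
        length, _ = craniocaudal_length(mask)
        frame = gland_frame_from_mask(mask)
        reo = reorient_to_gland_frame(mask, frame)
        # measure H/W at the maximal cross-section (a sphere has no poles)
        areas = reo.occupancy.sum(axis=(1, 2))
        h, w = height_width_at(reo, int(np.argmax(areas)))
        diag = np.linalg.norm(mask.spacing)
        assert abs(length - h) <= 2 * diag
        assert abs(length - w) <= 2 * diag

    def test_single_voxel_warns_zero(self):
        occ = np.zeros((3, 3, 3), dtype=int)
        occ[1, 1, 1] = 1
        with pytest.warns(UserWarning, match="single-voxel"):
            length, _ = craniocaudal_length(LabelMask(occ, (1, 1, 1)))
        assert length == 0.0


class TestGlandFrame:
    def test_frame_is_proper_rotation(self, dumbbell):
        frame = gland_frame_from_mask(dumbbell[1])
        R = frame.rotation
        assert np.allclose(R @ R.T, np.eye(3), atol=1e-9)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_invalid_frame_rejected(self):
        with pytest.raises(ValueError, match="orthonormal"):
            GlandFrame(np.array([1.0, 0, 0]), np.array([1.0, 0, 0]),
                       np.array([0, 0, 1.0]))


class TestReorientation:
    def test_aligned_gland_nearly_unchanged(self, dumbbell):
        _, mask, truth = dumbbell
        frame = gland_frame_from_mask(mask)
        reo = reorient_to_gland_frame(mask, frame)
        v0 = compute_volume(mask).total_volume_cm3
        v1 = compute_volume(reo).total_volume_cm3
        assert v1 == pytest.approx(v0, rel=0.01)

    def test_rotated_dumbbell_matches_unrotated(self):
        kw = dict(shape="dumbbell", lobe_radii_mm=(6.0, 5.0), neck_radius_mm=2.5,
                  lobe_separation_mm=18.0, spacing=(0.4, 0.4, 0.4))
        _, m0, _ = make_phantom(PhantomSpec(**kw))
        _, m1, _ = make_phantom(PhantomSpec(**kw, pose_deg=(20, 30, 10)))
        out = []
        for m in (m0, m1):
            reo = reorient_to_gland_frame(m, gland_frame_from_mask(m))
            st = locate_poles_and_isthmus(reo)
            out.append(height_width_at(reo, st.cranial)
                       + height_width_at(reo, st.caudal))
        for a, b in zip(*out):
            assert b == pytest.approx(a, rel=0.02, abs=0.5)

    def test_volume_preserved_across_pose(self):
        kw = dict(shape="dumbbell", lobe_radii_mm=(6.0, 5.0), neck_radius_mm=2.5,
                  lobe_separation_mm=18.0, spacing=(0.4, 0.4, 0.4))
        _, m1, _ = make_phantom(PhantomSpec(**kw, pose_deg=(20, 30, 10)))
        reo = reorient_to_gland_frame(m1, gland_frame_from_mask(m1))
        v0 = compute_volume(m1).total_volume_cm3
        assert compute_volume(reo).total_volume_cm3 == pytest.approx(v0, rel=0.01)


def _oracle_stations(mask, pole_window=0.5):
    """Exhaustive area-scan: poles = max area per window, isthmus = min
    between; same tie-break conventions, written independently."""
    cc = mask.axis_of("CC")
    other = tuple(a for a in range(3) if a != cc)
    areas = mask.occupancy.sum(axis=other).astype(int)
    occ = [int(z) for z in np.nonzero(areas)[0]]
    z0, z1 = occ[0], occ[-1]
    cran = [z for z in occ if z <= z0 + pole_window * (z1 - z0) + 1e-9]
    caud = [z for z in occ if z >= z1 - pole_window * (z1 - z0) - 1e-9]
    best_c = min(cran, key=lambda z: (-areas[z], z))
    best_d = min(caud, key=lambda z: (-areas[z], -z))
    mid = 0.5 * (best_c + best_d)
    between = [z for z in occ if best_c < z < best_d]
    isth = min(between, key=lambda z: (areas[z], abs(z - mid)))
    return best_c, best_d, isth


class TestPolesAndIsthmus:
    def test_dumbbell_lobes_and_neck(self, dumbbell):
        _, mask, truth = dumbbell
        reo = reorient_to_gland_frame(mask, gland_frame_from_mask(mask))
        st = locate_poles_and_isthmus(reo)
        d1, d2 = truth["lobe_diameters_mm"]
        h_c, w_c = height_width_at(reo, st.cranial)
        h_d, w_d = height_width_at(reo, st.caudal)
        h_i, w_i = height_width_at(reo, st.isthmus)
        tol = 2 * max(reo.spacing)
        assert {round(h_c), round(h_d)} == {round(d1), round(d2)}
        assert abs(h_i - truth["neck_diameter_mm"]) <= tol
        assert abs(w_i - truth["neck_diameter_mm"]) <= tol

    def test_uniform_cylinder_sections_all_equal(self):
        occ = np.zeros((20, 11, 11), dtype=int)
        yy, zz = np.meshgrid(np.arange(11) - 5, np.arange(11) - 5, indexing="ij")
        disc = (yy**2 + zz**2 <= 25).astype(int)
        occ[2:18] = disc
        mask = LabelMask(occ, (1, 1, 1), ("CC", "DV", "ML"))
        st = locate_poles_and_isthmus(mask)
        areas = occ.sum(axis=(1, 2))
        assert areas[st.cranial] == areas[st.caudal] == areas[st.isthmus]
        assert st.cranial == 2 and st.caudal == 17  # end-adjacent sections

    def test_monotone_cone_matches_area_scan_oracle(self):
        occ = np.zeros((20, 31, 31), dtype=int)
        yy, zz = np.meshgrid(np.arange(31) - 15, np.arange(31) - 15, indexing="ij")
        for i in range(20):
            r = 14 - 0.6 * i
            occ[i] = (yy**2 + zz**2 <= r**2).astype(int)
        mask = LabelMask(occ, (1, 1, 1), ("CC", "DV", "ML"))
        st = locate_poles_and_isthmus(mask)
        assert (st.cranial, st.caudal, st.isthmus) == _oracle_stations(mask)
        assert st.cranial == 0  # wide end
        assert st.isthmus == st.caudal - 1  # narrow-pole-adjacent

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_oracle_on_random_blobs(self, seed):
        rng = np.random.default_rng(seed)
        occ = np.zeros((15, 9, 9), dtype=int)
        for i in range(15):
            r = rng.integers(1, 5)
            yy, zz = np.meshgrid(np.arange(9) - 4, np.arange(9) - 4, indexing="ij")
            occ[i] = (yy**2 + zz**2 <= r**2).astype(int)
        mask = LabelMask(occ, (1, 1, 1), ("CC", "DV", "ML"))
        st = locate_poles_and_isthmus(mask)
        assert (st.cranial, st.caudal, st.isthmus) == _oracle_stations(mask)

    def test_too_few_stations_rejected(self):
        occ = np.zeros((4, 3, 3), dtype=int)
        occ[:, 1, 1] = 1
        with pytest.raises(ValueError, match="too small"):
            locate_poles_and_isthmus(LabelMask(occ, (1, 1, 1), ("CC", "DV", "ML")))


class TestHeightWidth:
    def test_circular_section(self):
        spec = PhantomSpec(shape="cylinder", radius_mm=5.0, height_mm=20.0,
                           spacing=(0.4, 0.4, 0.4), axes=("CC", "DV", "ML"))
        _, mask, truth = make_phantom(spec)
        st = locate_poles_and_isthmus(mask)
        h, w = height_width_at(mask, st.isthmus)
        assert h == pytest.approx(10.0, abs=0.5)
        assert w == pytest.approx(10.0, abs=0.5)

    def test_elliptical_section(self):
        # DV semi-axis 4 mm, ML semi-axis 2 mm -> H = 8, W = 4
        spec = PhantomSpec(shape="ellipsoid", semi_axes_mm=(15, 4, 2),
                           spacing=(0.4, 0.4, 0.4), axes=("CC", "DV", "ML"))
        _, mask, _ = make_phantom(spec)
        mid = mask.shape[0] // 2
        h, w = height_width_at(mask, mid)
        assert h == pytest.approx(8.0, abs=0.5)
        assert w == pytest.approx(4.0, abs=0.5)

    def test_rotated_ellipse_matches_projection_oracle(self):
        spec = PhantomSpec(shape="ellipsoid", semi_axes_mm=(15, 4, 2),
                           spacing=(0.4, 0.4, 0.4), axes=("CC", "DV", "ML"),
                           pose_deg=(45, 0, 0))  # in-plane rotation about CC
        _, mask, _ = make_phantom(spec)
        mid = mask.shape[0] // 2
        h, w = height_width_at(mask, mid)
        sect = mask.occupancy[mid]
        idx = np.argwhere(sect)
        oh = (idx[:, 0].max() - idx[:, 0].min() + 1) * 0.4
        ow = (idx[:, 1].max() - idx[:, 1].min() + 1) * 0.4
        assert h == pytest.approx(oh) and w == pytest.approx(ow)

    def test_empty_section_rejected(self):
        occ = np.zeros((6, 3, 3), dtype=int)
        occ[2:5, 1, 1] = 1
        mask = LabelMask(occ, (1, 1, 1), ("CC", "DV", "ML"))
        with pytest.raises(ValueError, match="empty cross-section"):
            height_width_at(mask, 0)


class TestAorticDiameter:
    def _cylinder(self, dv_r, ml_r, n=20):
        occ = np.zeros((n, 31, 31), dtype=int)
        yy, zz = np.meshgrid(np.arange(31) - 15, np.arange(31) - 15, indexing="ij")
        occ[5:15] = ((yy / dv_r) ** 2 + (zz / ml_r) ** 2 <= 1).astype(int)
        return LabelMask(occ, (1, 1, 1), ("CC", "DV", "ML"))

    def test_circular_aorta(self):
        mask = self._cylinder(5, 5)
        assert aortic_dorsoventral_diameter(mask, 10) == pytest.approx(11.0, abs=1.0)

    def test_elliptical_aorta_reads_dv_axis(self):
        mask = self._cylinder(6, 5)  # DV diameter 12, ML 10
        d = aortic_dorsoventral_diameter(mask, 10)
        assert d == pytest.approx(13.0, abs=1.0)
        assert d > aortic_dorsoventral_diameter(
            self._cylinder(5, 6), 10) - 3.0  # DV, not ML, is measured

    def test_off_station_is_error(self):
        mask = self._cylinder(5, 5)
        with pytest.raises(ValueError, match="empty at station"):
            aortic_dorsoventral_diameter(mask, 0)
        with pytest.raises(ValueError, match="outside"):
            aortic_dorsoventral_diameter(mask, 99)
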