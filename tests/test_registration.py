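import numpy as np
import pytest
from scipy import ndimage as ndi

from headmodel import registration as reg
from headmodel.phantom import (PhantomSpec, SensorCloud, Tissue,
                               make_layered_phantom, make_sensor_cloud)

from conftest import ball


@pytest.fixture(scope="module")
def bumpy_ellipsoid():
    """Asymmetric target mask (rotation/scale identifiable)."""
    n = 72
    g = np.ogrid[:n, :n, :n]
    c = (n - 1) / 2
    ell = ((g[0] - c) / 22) ** 2 + ((g[1] - c) / 17) ** 2 \
        + ((g[2] - c) / 13) ** 2 <= 1
    bump = sum((x - ci) ** 2 for x, ci in zip(g, (c + 19, c, c))) <= 36
    mask = ell | bump
    lm = np.argwhere(reg.contour(mask)).astype(float)[::10]
    return mask, lm, c, reg.distance_field(mask)


@pytest.fixture(scope="module")
def head_and_sensors():
    spec = PhantomSpec(shape=(72, 72, 72))
    vol, lab = make_layered_phantom(spec)
    H_m = lab.data != Tissue.BACKGROUND
    brain_c = np.argwhere(lab.mask(Tissue.WM, Tissue.GM)).mean(axis=0)
    return lab, H_m, brain_c


class TestDistanceField:
    def test_single_voxel(self):
        m = np.zeros((9, 9, 9), bool)
        m[4, 4, 4] = True
        df = reg.distance_field(m)
        assert df[4, 4, 4] == 0.0
        assert np.isclose(df[4, 4, 7], 3.0)

    def test_ball_center_value(self):
        m = ball(8, 24)
        df = reg.distance_field(m)
        # brute-force oracle: min distance from the center voxel to any
        # contour voxel
        pts = np.argwhere(reg.contour(m))
        want = np.linalg.norm(pts - [11, 11, 11], axis=1).min()
        assert np.isclose(df[11, 11, 11], want)
        assert abs(want - 8) <= 2.0  # discrete sphere surface roughness

    def test_zero_on_contour(self):
        m = ball(6, 16)
        df = reg.distance_field(m)
        assert np.all(df[reg.contour(m)] == 0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            reg.distance_field(np.zeros((4, 4, 4), bool))


class TestRigid:
    def test_identity_recovered(self, bumpy_ellipsoid):
        mask, lm, c, dist = bumpy_ellipsoid
        T = reg.rigid_fit(lm, mask, dist=dist)
        assert np.allclose(T.A, np.eye(3), atol=0.03)
        assert np.linalg.norm(T.t) < 0.5
        assert T.is_rigid(tol=1e-9)

    def test_translation_recovered(self, bumpy_ellipsoid):
        mask, lm, c, dist = bumpy_ellipsoid
        T = reg.rigid_fit(lm - [3.0, 0, 0], mask, dist=dist)
        assert np.allclose(T.A, np.eye(3), atol=0.03)
        assert abs(T.t[0] - 3.0) <= 0.5  # half the final grid step
        assert np.abs(T.t[1:]).max() <= 0.5

    def test_rotation_recovered(self, bumpy_ellipsoid):
        mask, lm, c, dist = bumpy_ellipsoid
        a = np.deg2rad(-10.0)
        R = np.array([[np.cos(a), -np.sin(a), 0],
                      [np.sin(a), np.cos(a), 0], [0, 0, 1]])
        T = reg.rigid_fit((lm - c) @ R.T + c, mask, dist=dist)
        got = np.rad2deg(np.arctan2(T.A[1, 0], T.A[0, 0]))
        assert abs(got - 10.0) <= 1.5  # within the final angular step

    def test_too_few_landmarks(self, bumpy_ellipsoid):
        mask, *_ = bumpy_ellipsoid
        with pytest.raises(ValueError):
            reg.rigid_fit(np.zeros((2, 3)), mask)


class TestAffine:
    def test_init_at_optimum_unchanged(self, bumpy_ellipsoid):
        mask, lm, c, dist = bumpy_ellipsoid
        T = reg.affine_fit(lm, mask, reg.LinearTransform.identity(),
                           dist=dist)
        assert np.allclose(T.A, np.eye(3), atol=1e-3)
        assert np.abs(T.t).max() < 0.1

    def test_isotropic_scale_recovered(self, bumpy_ellipsoid):
        mask, lm, c, dist = bumpy_ellipsoid
        lm_s = (lm - c) / 1.1 + c
        T = reg.affine_fit(lm_s, mask,
                           reg.rigid_fit(lm_s, mask, dist=dist), dist=dist)
        assert np.abs(np.diag(T.A) - 1.1).max() / 1.1 < 0.01

    def test_anisotropic_scale_recovered(self, bumpy_ellipsoid):
        mask, lm, c, dist = bumpy_ellipsoid
        S = np.diag([1 / 1.1, 1 / 0.9, 1.0])
        lm_s = (lm - c) @ S + c
        T = reg.affine_fit(lm_s, mask,
                           reg.rigid_fit(lm_s, mask, dist=dist), dist=dist)
        want = np.array([1.1, 0.9, 1.0])
        assert np.abs(np.diag(T.A) - want).max() < 0.02


class TestTPS:
    def test_identity_when_targets_equal_sources(self):
        rng = np.random.default_rng(0)
        src = rng.uniform(0, 30, (12, 3))
        t = reg.tps_fit(src, src)
        q = rng.uniform(0, 30, (50, 3))
        assert np.abs(t.apply(q) - q).max() < 1e-6

    def test_pure_translation_zero_kernel_weights(self):
        rng = np.random.default_rng(1)
        src = rng.uniform(0, 30, (10, 3))
        t = reg.tps_fit(src, src + [5.0, 0, 0])
        assert np.abs(t.kernel_weights).max() < 1e-9
        q = rng.uniform(0, 30, (20, 3))
        assert np.abs(t.apply(q) - (q + [5.0, 0, 0])).max() < 1e-6

    def test_affine_targets_zero_kernel_weights(self):
        rng = np.random.default_rng(2)
        src = rng.uniform(0, 30, (10, 3))
        A = np.array([[1.1, 0.05, 0], [0, 0.9, 0.02], [0.01, 0, 1.0]])
        t = reg.tps_fit(src, src @ A.T + [1, 2, 3])
        assert np.abs(t.kernel_weights).max() < 1e-9

    def test_exact_interpolation_random_landmarks(self):
        rng = np.random.default_rng(3)
        src = rng.uniform(0, 40, (10, 3))
        dst = src + rng.normal(0, 3, src.shape)
        t = reg.tps_fit(src, dst)
        assert np.abs(t.apply(src) - dst).max() < 1e-6

    def test_exactness_scales_to_many_landmarks(self):
        rng = np.random.default_rng(4)
        src = rng.uniform(0, 60, (500, 3))
        dst = src + rng.normal(0, 2, src.shape)
        t = reg.tps_fit(src, dst)
        assert np.abs(t.apply(src) - dst).max() < 1e-6

    def test_empty_points(self):
        src = np.array([[0.0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 10]])
        t = reg.tps_fit(src, src)
        assert reg.tps_apply(t, np.zeros((0, 3))).shape == (0, 3)

    def test_coincident_landmarks_fail(self):
        src = np.ones((5, 3))
        with pytest.raises(ValueError):
            reg.tps_fit(src, src + 1)

    def test_composition_order_preserved(self, bumpy_ellipsoid):
        # rigid -> affine -> TPS applied in sequence equals the composed map
        rng = np.random.default_rng(5)
        rig = reg.LinearTransform(np.column_stack(
            [reg._euler_matrix(*np.deg2rad([4, -3, 7])), [1.0, -2.0, 0.5]]))
        aff = reg.LinearTransform(np.column_stack(
            [np.diag([1.05, 0.95, 1.0]), [0.5, 0, -1.0]]))
        src = rng.uniform(0, 40, (8, 3))
        dst = src + rng.normal(0, 2, src.shape)
        tps = reg.tps_fit(src, dst)
        pts = rng.uniform(0, 40, (1000, 3))
        seq = tps.apply(aff.apply(rig.apply(pts)))
        lin = aff.compose(rig)
        comp = tps.apply(lin.apply(pts))
        assert np.abs(seq - comp).max() < 1e-6

    def test_linear_inverse_roundtrip(self):
        T = reg.LinearTransform(np.column_stack(
            [reg._euler_matrix(0.2, -0.1, 0.4) * 1.07, [3.0, -1.0, 2.0]]))
        pts = np.random.default_rng(6).uniform(0, 20, (40, 3))
        assert np.abs(T.inverse().apply(T.apply(pts)) - pts).max() < 1e-9


class TestLandmarkExtraction:
    def test_sets_disjoint_and_on_contours(self, head_and_sensors):
        lab, H_m, brain_c = head_and_sensors
        B_m = ndi.binary_closing(lab.mask(Tissue.WM, Tissue.GM),
                                 structure=np.ones((3, 3, 3)), iterations=2)
        E1 = lab.data == Tissue.EYEBALL
        labc, n = ndi.label(E1)
        inf, sup = reg.extract_mri_ct_landmarks(
            B_m, H_m, labc == 1, labc == 2)
        assert len(inf.points) > 0 and len(sup.points) > 0
        df_b = reg.distance_field(B_m)
        df_h = reg.distance_field(H_m)
        pts_i = inf.points.astype(int)
        pts_s = sup.points.astype(int)
        assert df_b[tuple(pts_i.T)].max() == 0.0
        assert df_h[tuple(pts_s.T)].max() == 0.0

    def test_fallback_without_eyeballs(self, head_and_sensors):
        lab, H_m, _ = head_and_sensors
        B_m = lab.mask(Tissue.WM, Tissue.GM)
        inf, sup = reg.extract_mri_ct_landmarks(B_m, H_m)
        assert len(inf.points) > 0 and len(sup.points) > 0


class TestSensorMapping:
    def test_all_sensors_projected_to_scalp(self, head_and_sensors):
        lab, H_m, brain_c = head_and_sensors
        cloud = make_sensor_cloud(lab, 256, radius_factor=2.0)
        mapped, ok = reg.sensors_to_head(cloud, H_m, brain_c)
        assert ok.all()
        df = reg.distance_field(H_m)
        d = ndi.map_coordinates(df, mapped.points.T, order=1)
        assert d.max() <= 1.0

    def test_angular_order_preserved(self, head_and_sensors):
        lab, H_m, brain_c = head_and_sensors
        cloud = make_sensor_cloud(lab, 128, radius_factor=2.0)
        mapped, _ = reg.sensors_to_head(cloud, H_m, brain_c)
        c0 = cloud.points - cloud.points.mean(axis=0)
        c1 = mapped.points - mapped.points.mean(axis=0)
        az0 = np.arctan2(c0[:, 1], c0[:, 0])
        az1 = np.arctan2(c1[:, 1], c1[:, 0])
        assert np.abs(np.angle(np.exp(1j * (az0 - az1)))).max() < 0.05

    def test_on_scalp_unchanged(self, head_and_sensors):
        lab, H_m, brain_c = head_and_sensors
        cloud = make_sensor_cloud(lab, 32)
        once, _ = reg.sensors_to_head(cloud, H_m, brain_c)
        twice, _ = reg.sensors_to_head(once, H_m, brain_c)
        assert np.abs(twice.points - once.points).max() <= 1.0

    def test_projection_is_outermost_intersection(self, head_and_sensors):
        # no sensor may land inside the head interior
        lab, H_m, brain_c = head_and_sensors
        cloud = make_sensor_cloud(lab, 64, radius_factor=2.0)
        mapped, _ = reg.sensors_to_head(cloud, H_m, brain_c)
        eroded = ndi.binary_erosion(H_m, iterations=3)
        inside = ndi.map_coordinates(eroded.astype(float),
                                     mapped.points.T, order=0)
        assert not inside.any()


class TestMriToGps:
    def test_on_scalp_cloud_near_identity(self, head_and_sensors):
        lab, H_m, brain_c = head_and_sensors
        cloud, _ = reg.sensors_to_head(make_sensor_cloud(lab, 64), H_m,
                                       brain_c)
        tps, aligned = reg.mri_to_gps(H_m, brain_c, cloud, mode="auto")
        assert np.abs(aligned - cloud.points).max() < 1.0

    def test_offset_cloud_lands_on_deformed_scalp(self, head_and_sensors):
        lab, H_m, brain_c = head_and_sensors
        on, _ = reg.sensors_to_head(make_sensor_cloud(lab, 64), H_m,
                                    brain_c)
        pts = on.points
        c = pts.mean(axis=0)
        radial = (pts - c) / np.linalg.norm(pts - c, axis=1)[:, None]
        cloud = SensorCloud(list(on.labels), pts + 5 * radial,
                            on.fiducials)
        tps, aligned = reg.mri_to_gps(H_m, brain_c, cloud, mode="auto")
        # the TPS maps its scalp sources exactly onto the aligned sensors
        src = tps.sources
        assert np.abs(tps.apply(src) - aligned[:len(src)]).max() < 1.0

    def test_fiducial_mode_requires_fiducials(self, head_and_sensors):
        lab, H_m, brain_c = head_and_sensors
        bare = SensorCloud([f"E{i}" for i in range(8)],
                           np.random.default_rng(0).uniform(10, 60, (8, 3)))
        with pytest.raises(ValueError):
            reg.mri_to_gps(H_m, brain_c, bare, mode="3-fiducial")

    def test_three_fiducial_initialization(self, head_and_sensors):
        lab, H_m, brain_c = head_and_sensors
        on, _ = reg.sensors_to_head(make_sensor_cloud(lab, 32), H_m,
                                    brain_c)
        # displace the cloud rigidly; fiducials displaced identically
        shift = np.array([4.0, -3.0, 2.0])
        moved = SensorCloud(list(on.labels), on.points + shift,
                            {k: v + shift for k, v in on.fiducials.items()})
        tps, aligned = reg.mri_to_gps(
            H_m, brain_c, moved, mode="3-fiducial",
            mri_fiducials=dict(on.fiducials))
        assert np.abs(aligned - on.points).max() < 2.0


class TestAtlasSkullFit:
    @staticmethod
    def _masks(scale, n=80):
        g = np.ogrid[:n, :n, :n]
        c = (n - 1) / 2
        r = np.sqrt(sum((x - c) ** 2 for x in g))
        return dict(brain=r < 19 * scale,
                    skull=(r >= 22 * scale) & (r < 25 * scale),
                    head=r < 29 * scale)

    def test_identity_fit(self):
        atlas = self._masks(1.0)
        tps, params = reg.atlas_skull_fit(atlas, self._masks(1.0))
        assert abs(params.global_ratio - 1.0) < 0.1
        q = np.array([[25.0, 40.0, 50.0], [40.0, 40.0, 40.0]])
        assert np.abs(tps.apply(q) - q).max() < 1.0
        assert params.frac_outside_brain >= 0.90

    def test_scaled_subject(self):
        atlas = self._masks(1.0)
        subj = self._masks(1.15)
        tps, params = reg.atlas_skull_fit(atlas, subj)
        assert abs(params.global_ratio - 1.15) < 0.1
        assert params.frac_outside_brain >= 0.90
        # warp the atlas skull and compare with the scaled truth
        pts = np.argwhere(atlas["skull"]).astype(float)
        w = np.round(tps.apply(pts)).astype(int)
        ok = np.all((w >= 0) & (w < 80), axis=1)
        mask = np.zeros((80, 80, 80), bool)
        mask[tuple(w[ok].T)] = True
        mask = ndi.binary_closing(mask, structure=np.ones((3, 3, 3)))
        inter = (mask & subj["skull"]).sum()
        d = 2 * inter / (mask.sum() + subj["skull"].sum())
        assert d >= 0.85
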