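import numpy as np
import pytest

from headmodel import rt
from headmodel.phantom import PhantomSpec, Tissue, Volume, degraded_phantom


def two_plateau(z_hi=150.0, z_lo=105.0, split=8, n=(20, 20, 20)):
    z = np.full(n, z_hi)
    z[:, :, :split] = z_lo
    return z


class TestSmooth:
    def test_constant_identity(self):
        z = np.full((8, 8, 8), 42.0)
        assert np.allclose(rt.smooth(z, 1.0), z)

    def test_radius_zero_identity(self):
        z = np.random.default_rng(0).uniform(0, 1, (8, 8, 8))
        assert np.array_equal(rt.smooth(z, 0.0), z)

    def test_impulse_mass_preserved(self):
        z = np.zeros((21, 21, 21))
        z[10, 10, 10] = 7.0
        assert abs(rt.smooth(z, 1.0).sum() - 7.0) < 1e-6

    def test_accepts_volume(self):
        v = Volume(np.ones((6, 6, 6)))
        assert rt.smooth(v, 1.0).shape == (6, 6, 6)


class TestGradientPath:
    def test_global_max_is_fixed_point(self):
        z = np.zeros((7, 7, 7))
        z[3, 3, 3] = 10.0
        path, dists = rt.trace_gradient_path(z, (3, 3, 3))
        assert path == [(3, 3, 3)] and dists == [0.0]

    def test_ramp_follows_axis(self):
        z = np.tile(np.arange(9.0)[None, None, :], (5, 5, 1))
        path, dists = rt.trace_gradient_path(z, (2, 2, 0))
        assert path == [(2, 2, k) for k in range(9)]
        assert np.allclose(dists, np.arange(9.0))

    def test_tie_breaks_lexicographic(self):
        # two equal ascent options: the first offset in lexicographic
        # order wins deterministically
        z = np.zeros((5, 5, 5))
        z[1, 2, 2] = 5.0
        z[3, 2, 2] = 5.0
        path, _ = rt.trace_gradient_path(z, (2, 2, 2), max_len=2)
        assert path[1] == (1, 2, 2)


class TestDifferentiation:
    def test_gm_relabeled_below_threshold(self):
        # ratio 105/150 = 0.70 < 0.85; the GM slab is thin enough that the
        # smoothed boundary gradient reaches every GM voxel (on noiseless
        # plateaus beyond the blur reach the gradient path has no ascent,
        # so relabeling needs either texture or proximity to the boundary)
        z = rt.smooth(two_plateau(split=5, n=(20, 20, 16)), 1.0)
        roi = np.ones(z.shape, bool)
        lab = rt.gm_wm_differentiate(z, roi, 0.85, 6.0)
        truth_gm = np.zeros(z.shape, bool)
        truth_gm[:, :, :5] = True
        got_gm = lab == Tissue.GM
        assert (got_gm == truth_gm).mean() > 0.95
        assert np.all(got_gm[:, :, :4])  # GM interior fully relabeled

    def test_no_relabel_when_threshold_below_ratio(self):
        # 0.70 > 0.60: nothing may flip to GM
        z = rt.smooth(two_plateau(), 1.0)
        roi = np.ones(z.shape, bool)
        lab = rt.gm_wm_differentiate(z, roi, 0.60, 6.0)
        assert (lab == Tissue.GM).sum() == 0

    def test_uniform_volume_never_relabels(self):
        z = np.full((12, 12, 12), 100.0)
        roi = np.ones(z.shape, bool)
        lab = rt.gm_wm_differentiate(z, roi, 0.95, 6.0)
        assert (lab == Tissue.GM).sum() == 0

    def test_invalid_threshold_rejected(self):
        z = np.ones((6, 6, 6))
        with pytest.raises(ValueError):
            rt.gm_wm_differentiate(z, np.ones_like(z, bool), 1.2, 4.0)

    def test_csf_relabeled_gm_kept(self):
        # three plateaus 40 / 105 / 150: CSF/WM ratio 0.267 < 0.45 flips,
        # GM/WM ratio 0.70 >= 0.45 stays
        z = np.full((20, 20, 24), 150.0)
        z[:, :, :12] = 105.0
        z[:, :, :6] = 40.0
        zs = rt.smooth(z, 1.0)
        roi = np.ones(z.shape, bool)
        lab = rt.gm_wm_differentiate(zs, roi, 0.85, 6.0)
        lab = rt.csf_gm_differentiate(zs, lab, 0.45, 12.0, t_gw=0.85)
        csf = lab == Tissue.CSF
        truth_csf = np.zeros(z.shape, bool)
        truth_csf[:, :, :6] = True
        assert (csf == truth_csf).mean() > 0.95
        gm = lab == Tissue.GM
        assert gm[:, :, 7:11].mean() > 0.9  # GM interior stays GM

    def test_low_tcw_relabels_nothing(self):
        z = np.full((16, 16, 18), 150.0)
        z[:, :, :9] = 105.0
        zs = rt.smooth(z, 1.0)
        roi = np.ones(z.shape, bool)
        lab = rt.gm_wm_differentiate(zs, roi, 0.85, 6.0)
        out = rt.csf_gm_differentiate(zs, lab, 0.1, 12.0, t_gw=0.85)
        assert (out == Tissue.CSF).sum() == 0

    def test_ordering_constraint_rejected(self):
        z = np.ones((6, 6, 6))
        lab = np.full(z.shape, Tissue.GM, np.int16)
        with pytest.raises(ValueError):
            rt.csf_gm_differentiate(z, lab, 0.9, 10.0, t_gw=0.85)


class TestObjective:
    def test_piecewise_constant_is_zero(self):
        z = two_plateau()
        lab = np.where(z > 120, Tissue.WM, Tissue.GM).astype(np.int16)
        h, hw, hg, hc = rt.rt_objective(z, lab)
        assert h == 0.0

    def test_hand_enumerated_1d(self):
        z = np.zeros((3, 1, 1))
        z[:, 0, 0] = [10, 12, 11]
        lab = np.full(z.shape, Tissue.WM, np.int16)
        h, hw, hg, hc = rt.rt_objective(z, lab)
        assert hw == 3.0 and hg == 0.0 and hc == 0.0

    def test_weights_select_terms(self):
        z = np.zeros((3, 1, 1))
        z[:, 0, 0] = [10, 12, 11]
        lab = np.full(z.shape, Tissue.WM, np.int16)
        h, hw, *_ = rt.rt_objective(z, lab, weights=(1.0, 0.0, 0.0))
        assert h == hw


class TestOptimize:
    def test_single_pair_returned(self):
        z = rt.smooth(two_plateau(), 1.0)
        roi = np.ones(z.shape, bool)
        p = rt.RTParams(t_gw_grid=(0.85,), t_cw_grid=(0.45,))
        (tg, tc), labels, _ = rt.optimize_thresholds(z, roi, p)
        assert (tg, tc) == (0.85, 0.45)

    def test_all_invalid_pairs_rejected(self):
        z = np.ones((6, 6, 6))
        p = rt.RTParams(t_gw_grid=(0.3,), t_cw_grid=(0.5,))
        with pytest.raises(ValueError):
            rt.optimize_thresholds(z, np.ones_like(z, bool), p)

    def test_matches_reference_differentiation(self):
        # the table-driven search must equal running the two passes
        spec = PhantomSpec(shape=(48, 48, 48), r_wm=12, r_gm=15, r_csf=17,
                           r_skull=19, r_flesh=22, eyeballs=False,
                           inu_percent=20.0, seed=2)
        vol, lab_t = degraded_phantom(spec)
        z = rt.smooth(vol.data, 1.0)
        roi = lab_t.mask(Tissue.WM, Tissue.GM, Tissue.CSF)
        p = rt.RTParams(t_gw_grid=(0.7, 0.85), t_cw_grid=(0.3, 0.45))
        (tg, tc), labels, _ = rt.optimize_thresholds(z, roi, p)
        ref = rt.gm_wm_differentiate(z, roi, tg, p.d_gw)
        ref = rt.csf_gm_differentiate(z, ref, tc, p.d_cw, t_gw=tg)
        assert np.array_equal(labels, ref)

    def test_noiseless_phantom_recovered(self):
        spec = PhantomSpec(shape=(64, 64, 64), inu_percent=20.0, seed=1)
        vol, lab_t = degraded_phantom(spec)
        z = rt.smooth(vol.data, 1.0)
        roi = lab_t.mask(Tissue.WM, Tissue.GM, Tissue.CSF)
        (tg, tc), labels, _ = rt.optimize_thresholds(z, roi, rt.RTParams())
        for code in (Tissue.WM, Tissue.GM, Tissue.CSF):
            seg, tr = labels == code, lab_t.data == code
            d = 2 * (seg & tr).sum() / (seg.sum() + tr.sum())
            assert d >= 0.97, code

    def test_unused_extreme_candidate_keeps_argmin(self):
        spec = PhantomSpec(shape=(48, 48, 48), r_wm=12, r_gm=15, r_csf=17,
                           r_skull=19, r_flesh=22, eyeballs=False,
                           inu_percent=20.0, seed=2)
        vol, lab_t = degraded_phantom(spec)
        z = rt.smooth(vol.data, 1.0)
        roi = lab_t.mask(Tissue.WM, Tissue.GM, Tissue.CSF)
        base = rt.RTParams(t_gw_grid=(0.7, 0.8, 0.85),
                           t_cw_grid=(0.3, 0.45))
        aug = rt.RTParams(t_gw_grid=(0.51, 0.7, 0.8, 0.85),
                          t_cw_grid=(0.21, 0.3, 0.45))
        pair1, *_ = rt.optimize_thresholds(z, roi, base)
        pair2, *_ = rt.optimize_thresholds(z, roi, aug)
        assert pair1 == pair2

    def test_global_scale_invariance_exact(self):
        spec = PhantomSpec(shape=(48, 48, 48), r_wm=12, r_gm=15, r_csf=17,
                           r_skull=19, r_flesh=22, eyeballs=False,
                           inu_percent=20.0, noise_percent=3.0, seed=2)
        vol, lab_t = degraded_phantom(spec)
        z = rt.smooth(vol.data, 1.0)
        roi = lab_t.mask(Tissue.WM, Tissue.GM, Tissue.CSF)
        p = rt.RTParams(t_gw_grid=(0.7, 0.85), t_cw_grid=(0.3, 0.45))
        pair1, lab1, _ = rt.optimize_thresholds(z, roi, p)
        pair2, lab2, _ = rt.optimize_thresholds(z * 2.0, roi, p)
        assert pair1 == pair2
        assert np.array_equal(lab1, lab2)

    def test_never_relabels_outside_roi(self):
        z = rt.smooth(two_plateau(), 1.0)
        roi = np.zeros(z.shape, bool)
        roi[4:16, 4:16, 4:16] = True
        lab = rt.gm_wm_differentiate(z, roi, 0.85, 6.0)
        assert np.all(lab[~roi] == Tissue.BACKGROUND)
        assert set(np.unique(lab[roi])) <= {Tissue.WM, Tissue.GM,
                                            Tissue.CSF}


class TestScheme2:
    def test_bimodal_threshold_matches_sweep_oracle(self):
        # exhaustive sweep oracle over all distinct intensity cuts
        rng = np.random.default_rng(5)
        z = np.where(rng.random((14, 14, 14)) < 0.5, 40.0, 150.0)
        z += rng.normal(0, 1, z.shape)
        roi = np.ones(z.shape, bool)
        W0, t = rt.seed_wm_by_threshold(z, roi, min_card=10)

        def objective(thr):
            w = z >= thr
            fe = m = 0.0
            dww = []
            for ax in range(3):
                sl0 = [slice(None)] * 3
                sl1 = [slice(None)] * 3
                sl0[ax] = slice(0, -1)
                sl1[ax] = slice(1, None)
                a, b = z[tuple(sl0)], z[tuple(sl1)]
                wa, wb = w[tuple(sl0)], w[tuple(sl1)]
                cross = wa != wb
                fe += np.abs(a - b)[cross].sum()
                m += cross.sum()
                dww.extend(np.abs(a - b)[wa & wb].ravel())
            dww = np.sort(dww)[::-1]
            fr = dww[:int(m)].sum()
            return fe - fr

        # the returned threshold's objective matches the best over a fine
        # sweep (within the quantile grid resolution)
        sweep = [objective(t0) for t0 in np.quantile(z[roi],
                                                     np.linspace(0.02, 0.98,
                                                                 64))]
        assert objective(t) >= max(sweep) - 1e-6
        assert W0.sum() >= 10
        # W0 is the bright plateau
        assert (z[W0] > 100).mean() > 0.99

    def test_min_cardinality_failure(self):
        z = np.full((8, 8, 8), 50.0)
        with pytest.raises(ValueError):
            rt.seed_wm_by_threshold(z, np.ones_like(z, bool),
                                    min_card=10 ** 6)

    def test_dilate_sharp_boundary_adds_nothing(self):
        z = two_plateau()
        roi = np.ones(z.shape, bool)
        W0 = z > 120
        lab = rt.rt_dilate(z, roi, W0, 0.85)
        assert np.array_equal(lab == Tissue.WM, W0)

    def test_dilate_covers_biased_wm(self):
        # WM with a +-10 % linear shading: the local reference adapts and
        # the dilation recovers the full region
        n = 24
        ramp = np.linspace(0.9, 1.1, n)[None, None, :]
        z = np.full((n, n, n), 150.0) * ramp
        z[:, :8, :] = 105.0 * np.ones((n, 8, n)) * ramp
        roi = np.ones(z.shape, bool)
        W0 = np.zeros_like(roi)
        W0[:, 12:, 8:16] = True  # seed in the WM half
        lab = rt.rt_dilate(z, roi, W0, 0.85)
        wm_truth = np.zeros_like(roi)
        wm_truth[:, 8:, :] = True
        got = lab == Tissue.WM
        assert (got & wm_truth).sum() / wm_truth.sum() > 0.98
        assert (got & ~wm_truth).sum() < 0.02 * wm_truth.sum()

    def test_dilate_threshold_zero_floods_roi(self):
        z = two_plateau()
        roi = np.ones(z.shape, bool)
        W0 = z > 120
        lab = rt.rt_dilate(z, roi, W0, 1e-9)
        assert np.all(lab[roi] == Tissue.WM)

    def test_empty_seed_rejected(self):
        z = two_plateau()
        with pytest.raises(ValueError):
            rt.rt_dilate(z, np.ones(z.shape, bool),
                         np.zeros(z.shape, bool), 0.85)
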