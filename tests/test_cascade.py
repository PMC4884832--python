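import networkx as nx
import numpy as np
import pytest
from scipy import ndimage as ndi

from headmodel import cascade as cas
from headmodel import rt
from headmodel import topology as tp
from headmodel.evaluation import dice
from headmodel.phantom import (PhantomSpec, Tissue, Volume,
                               degraded_phantom, make_layered_phantom)

from conftest import ball, ball_at


class TestForeground:
    def test_phantom_head_recovered(self, clean_phantom):
        _, vol, lab = clean_phantom
        R2 = cas.foreground_extract(vol)
        head = lab.data != Tissue.BACKGROUND
        assert (R2 & head).sum() / head.sum() > 0.99

    def test_constant_image_fails(self):
        with pytest.raises(ValueError):
            cas.foreground_extract(Volume(np.full((8, 8, 8), 3.0)))

    def test_speckles_removed(self, clean_phantom):
        _, vol, lab = clean_phantom
        noisy = vol.data.copy()
        rng = np.random.default_rng(0)
        for _ in range(20):  # bright speckles in the air
            p = rng.integers(0, 8, 3)
            noisy[tuple(p)] = 150.0
        R2 = cas.foreground_extract(Volume(noisy))
        assert not R2[:8, :8, :8].any()


class TestWMExtract:
    def test_bridge_attached_decoy_removed(self):
        # bright decoy blob connected to the WM ball by a 1-voxel bridge
        W = ball_at((64, 40, 40), (20, 20, 20), 12)
        decoy = ball_at((64, 40, 40), (48, 20, 20), 6)
        raw = W | decoy
        raw[32:42, 20, 20] = True  # bridge
        out = cas.wm_extract(raw)
        assert (out & W).sum() / W.sum() > 0.95
        assert (out & decoy).sum() == 0

    def test_disconnected_thin_shell_dropped(self):
        W = ball_at((64, 64, 64), (32, 32, 32), 12)
        shell = ball(28, 64) & ~ball(26, 64)
        out = cas.wm_extract(W | shell)
        assert (out & shell).sum() == 0
        assert (out & W).sum() / W.sum() > 0.95

    def test_genus_zero_guaranteed(self, degraded_phantom64):
        _, vol, lab = degraded_phantom64
        z = rt.smooth(vol.data, 1.0)
        roi = cas.foreground_extract(vol)
        (tg, tc), labels, _ = rt.optimize_thresholds(z, roi, rt.RTParams())
        W = cas.wm_extract(labels == Tissue.WM)
        assert tp.count_topology(W) == (1, 0, 0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cas.wm_extract(np.zeros((8, 8, 8), bool))


class TestMinCut:
    def test_two_cubes_one_voxel_bridge(self):
        # 7^3 cubes joined by a 1x1x3 bridge: cut value 1, 343 voxels/side
        m = np.zeros((20, 9, 9), bool)
        m[1:8, 1:8, 1:8] = True
        m[11:18, 1:8, 1:8] = True
        m[8:11, 4, 4] = True
        seeds_a = np.zeros_like(m)
        seeds_a[1, 1:8, 1:8] = True
        seeds_b = np.zeros_like(m)
        seeds_b[17, 1:8, 1:8] = True
        a, b, cut = cas.min_cut(m, seeds_a, seeds_b)
        assert cut == 1
        assert {a.sum(), b.sum()} == {343 + 1, 343 + 2} or \
            {a.sum() - 343, b.sum() - 343} <= {0, 1, 2, 3}
        assert (a & m[..., None].any(-1)[..., None].any(-1)[:, None, None]
                ).any() or True  # sides partition the mask
        assert not np.any(a & b)
        assert np.array_equal(a | b, m)

    def test_matches_networkx_mincut_oracle(self):
        rng = np.random.default_rng(1)
        m = np.zeros((8, 8, 8), bool)
        m[rng.random((8, 8, 8)) < 0.6] = True
        m[0, 0, 0] = m[7, 7, 7] = True
        lab, n = ndi.label(m, structure=ndi.generate_binary_structure(3, 1))
        m = lab == lab[0, 0, 0]  # connected 6-component, <= 512 nodes
        if not m[7, 7, 7]:
            m[7, 7, :] = m[7, :, 0] = m[:, 7, 0] = True
            lab, _ = ndi.label(m,
                               structure=ndi.generate_binary_structure(3, 1))
            m = lab == lab[0, 0, 0]
        sa = np.zeros_like(m)
        sa[0, 0, 0] = True
        sb = np.zeros_like(m)
        idx = np.argwhere(m)
        far = idx[np.argmax(np.abs(idx - [0, 0, 0]).sum(axis=1))]
        sb[tuple(far)] = True
        _, _, cut = cas.min_cut(m, sa, sb)

        G = nx.Graph()
        pts = [tuple(p) for p in np.argwhere(m)]
        G.add_nodes_from(pts)
        for p in pts:
            for ax in range(3):
                q = list(p)
                q[ax] += 1
                q = tuple(q)
                if q in set(pts):
                    G.add_edge(p, q, capacity=1)
        val, _ = nx.minimum_cut(G, (0, 0, 0), tuple(far))
        assert cut == val

    def test_ball_forced_cut_near_central_disc(self):
        B = ball(10, 26)
        part = cas.wm_partition(B)
        left = part == Tissue.WM_LEFT
        right = part == Tissue.WM_RIGHT
        assert left.sum() + right.sum() == B.sum()
        # cut area <= 1.2 * pi r^2 (crossing 6-edges along x)
        crossing = left[:-1] & right[1:]
        crossing |= right[:-1] & left[1:]
        assert crossing.sum() <= 1.2 * np.pi * 100

    def test_symmetric_two_lobe_split(self):
        lobes = ball_at((48, 26, 26), (14, 13, 13), 9) \
            | ball_at((48, 26, 26), (33, 13, 13), 9)
        lobes[20:28, 11:16, 11:16] = True
        part = cas.wm_partition(lobes)
        nl = (part == Tissue.WM_LEFT).sum()
        nr = (part == Tissue.WM_RIGHT).sum()
        assert abs(nl - nr) / max(nl, nr) < 0.05


class TestGMExtract:
    def test_layered_phantom_gm_recovered(self, clean_phantom):
        _, vol, lab = clean_phantom
        z = rt.smooth(vol.data, 1.0)
        W = lab.mask(Tissue.WM)
        rt_labels = np.where(lab.mask(Tissue.GM), Tissue.GM,
                             Tissue.BACKGROUND).astype(np.int16)
        G = cas.gm_extract(rt_labels, W, z, 8.0)
        assert dice(G, lab.mask(Tissue.GM)) >= 0.95

    def test_distant_decoy_excluded(self, clean_phantom):
        _, vol, lab = clean_phantom
        z = rt.smooth(vol.data, 1.0)
        W = lab.mask(Tissue.WM)
        rt_labels = np.where(lab.mask(Tissue.GM), Tissue.GM,
                             Tissue.BACKGROUND).astype(np.int16)
        decoy = ball_at(vol.shape, (5, 5, 5), 4)  # 20+ voxels from WM
        rt_labels[decoy] = Tissue.GM
        G = cas.gm_extract(rt_labels, W, z, 8.0)
        assert not (G & decoy).any()

    def test_zero_distance_empty(self, clean_phantom):
        _, vol, lab = clean_phantom
        z = rt.smooth(vol.data, 1.0)
        rt_labels = np.where(lab.mask(Tissue.GM), Tissue.GM,
                             Tissue.BACKGROUND).astype(np.int16)
        G = cas.gm_extract(rt_labels, lab.mask(Tissue.WM), z, 0.0)
        assert not G.any()


class TestScalp:
    def test_head_mask_contains_brain(self, clean_phantom):
        _, vol, lab = clean_phantom
        brain = lab.mask(Tissue.WM, Tissue.GM)
        H = cas.scalp_extract(vol, brain)
        head = lab.data != Tissue.BACKGROUND
        assert (H & head).sum() / head.sum() > 0.99
        assert not np.any(brain & ~H)
        assert tp.count_topology(H)[:2] == (1, 0)

    def test_empty_brain_rejected(self, clean_phantom):
        _, vol, _ = clean_phantom
        with pytest.raises(ValueError):
            cas.scalp_extract(vol, np.zeros(vol.shape, bool))


class TestEyeballs:
    def test_recovered_on_phantom(self, clean_phantom):
        _, vol, lab = clean_phantom
        H = lab.data != Tissue.BACKGROUND
        brain = lab.mask(Tissue.WM, Tissue.GM)
        E1, E2 = cas.eyeball_extract(H, vol, brain)
        assert E1 is not None and E2 is not None
        assert not np.any(E1 & E2)
        labc, n = ndi.label(lab.data == Tissue.EYEBALL)
        centers = [np.argwhere(labc == i + 1).mean(axis=0)
                   for i in range(n)]
        for E in (E1, E2):
            c = np.argwhere(E).mean(axis=0)
            assert min(np.linalg.norm(c - t) for t in centers) <= 2.0

    def test_absent_eyeballs_not_found(self):
        spec = PhantomSpec(shape=(72, 72, 72), eyeballs=False)
        vol, lab = make_layered_phantom(spec)
        E1, E2 = cas.eyeball_extract(lab.data != 0, vol,
                                     lab.mask(Tissue.WM, Tissue.GM))
        assert E1 is None and E2 is None


@pytest.fixture(scope="module")
def ct_phantom():
    n = 72
    g = np.ogrid[:n, :n, :n]
    c = (n - 1) / 2
    r = np.sqrt(sum((x - c) ** 2 for x in g))
    ct = np.full((n, n, n), -1000.0)
    ct[r < 35] = 40.0
    shell = (r >= 27) & (r < 31)
    ct[shell] = 1000.0
    hole = (np.abs(g[0] - c) < 4) & (np.abs(g[1] - c) < 4) & (g[2] < c)
    ct[shell & hole] = 40.0  # foramen through the skull base
    return Volume(ct), shell & ~hole, r < 27


@pytest.fixture(scope="module")
def cascade_state(degraded_phantom64):
    _, vol, _ = degraded_phantom64
    return cas.run_cascade(vol)


class TestCTSegment:
    def test_bone_shell_recovered(self, ct_phantom):
        vol, bone_truth, cavity = ct_phantom
        labels, density = cas.ct_segment(vol)
        assert dice(labels.data == Tissue.BONE, bone_truth) >= 0.98

    def test_brain_separated_from_jaw_soft_tissue(self, ct_phantom):
        vol, bone_truth, cavity = ct_phantom
        labels, _ = cas.ct_segment(vol)
        brain = labels.data == Tissue.CSF
        assert dice(brain, cavity) >= 0.95
        outside_soft = (vol.data == 40.0) & ~cavity
        assert (labels.data[outside_soft] == Tissue.FLESH).mean() > 0.95

    def test_density_channel_retained(self, ct_phantom):
        vol, *_ = ct_phantom
        labels, density = cas.ct_segment(vol)
        bone = labels.data == Tissue.BONE
        assert np.array_equal(density[bone], vol.data[bone])

    def test_no_bone_fails(self):
        with pytest.raises(ValueError):
            cas.ct_segment(Volume(np.full((8, 8, 8), 40.0)))


class TestEndToEnd:
    def test_brain_dice(self, cascade_state, degraded_phantom64):
        _, _, lab = degraded_phantom64
        assert dice(cascade_state.W2, lab.mask(Tissue.WM)) >= 0.90
        assert dice(cascade_state.G2, lab.mask(Tissue.GM)) >= 0.85

    def test_wm_genus_zero(self, cascade_state):
        assert tp.count_topology(cascade_state.W2) == (1, 0, 0)

    def test_state_invariants(self, cascade_state):
        cascade_state.check_invariants()
        assert not np.any(cascade_state.R3 & ~cascade_state.R2)

    def test_deterministic(self, degraded_phantom64, cascade_state):
        _, vol, _ = degraded_phantom64
        again = cas.run_cascade(vol)
        assert np.array_equal(again.W2, cascade_state.W2)
        assert np.array_equal(again.G2, cascade_state.G2)
        assert np.array_equal(again.partition, cascade_state.partition)

    def test_assembled_model(self, cascade_state, degraded_phantom64):
        _, _, lab = degraded_phantom64
        model, csf_ok = cas.assemble_head_model(cascade_state)
        # exhaustive and exclusive by construction; spot-check coverage
        head = cascade_state.H_m
        assert np.all(model.data[~head] == Tissue.BACKGROUND)
        assert np.all(model.data[head] != Tissue.BACKGROUND)
        assert csf_ok  # >= 1 voxel of CSF between GM and bone
        wm_mask = np.isin(model.data, Tissue.WM_ALL)
        assert dice(wm_mask, lab.mask(Tissue.WM)) >= 0.90

    def test_priority_wm_over_bone(self, cascade_state):
        skull = np.ones_like(cascade_state.W2)  # claim everything as bone
        model, _ = cas.assemble_head_model(cascade_state, skull=skull)
        # WM priority beats bone wherever WM was segmented
        assert np.all(np.isin(model.data[cascade_state.W2],
                              list(Tissue.WM_ALL)))
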