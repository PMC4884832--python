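"""Segmentation cascade: foreground -> relative thresholding -> WM
extraction -> WM partition -> GM extraction -> scalp -> eyeballs, plus CT
segmentation and head-model assembly.

The cascade takes the whole image as the first region of interest R1,
splits it into foreground/background (R2), classifies R2 into WM/GM/CSF by
relative thresholding, extracts a topology-corrected WM volume W1, derives
an initial GM volume G1, refines the classification on R3 = W1 u G1 with
the seeded-dilation scheme, re-extracts WM (W2), partitions W2 into
hemispheres (and optionally a cerebellar compartment) by minimum cut, and
finally extracts G2, the head mask and the eyeballs.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
from scipy import ndimage as ndi
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_flow
from skimage.filters import threshold_multiotsu, threshold_otsu

from . import cell_complex as ccm
from . import rt as rtmod
from . import topology as tp
from .phantom import LabelVolume, Tissue, Volume

_STRUCT26 = np.ones((3, 3, 3), bool)
_STRUCT6 = ndi.generate_binary_structure(3, 1)


@dataclass
class CascadeConfig:
    rt: rtmod.RTParams = dfield(default_factory=rtmod.RTParams)
    gm_d_max: float = 8.0
    split_cerebellum: bool = False
    detect_eyeballs: bool = True
    eyeball_radii: tuple = (4, 5, 6)


@dataclass
class CascadeState:
    """Intermediate and final volumes of the segmentation cascade."""

    R1: np.ndarray | None = None
    R2: np.ndarray | None = None
    R3: np.ndarray | None = None
    W1: np.ndarray | None = None
    W2: np.ndarray | None = None
    G1: np.ndarray | None = None
    G2: np.ndarray | None = None
    H_m: np.ndarray | None = None
    E1: np.ndarray | None = None
    E2: np.ndarray | None = None
    rt_labels: np.ndarray | None = None
    thresholds: tuple | None = None
    partition: np.ndarray | None = None  # labeled W2/G2 compartments

    def check_invariants(self) -> None:
        if self.R3 is not None and self.R2 is not None:
            assert not np.any(self.R3 & ~self.R2), "R3 must lie inside R2"
        if self.W2 is not None and self.G2 is not None:
            assert not np.any(self.W2 & self.G2), "W2 and G2 overlap"
        if self.E1 is not None and self.E2 is not None:
            assert not np.any(self.E1 & self.E2), "eyeballs overlap"


# ---------------------------------------------------------------------------
# foreground and scalp
# ---------------------------------------------------------------------------


def foreground_extract(vol: Volume | np.ndarray) -> np.ndarray:
    """Two-class intensity split (Otsu) with morphological cleanup: the
    largest connected component, holes filled."""
    data = vol.data if isinstance(vol, Volume) else np.asarray(vol, float)
    if not np.all(np.isfinite(data)):
        raise ValueError("volume must be finite")
    if data.max() == data.min():
        raise ValueError("constant image has no foreground")
    try:
        # the lowest of several Otsu cuts separates air from the darkest
        # tissue; a single two-class cut can land between tissue modes
        thr = float(threshold_multiotsu(data, classes=4)[0])
    except ValueError:
        thr = float(threshold_otsu(data))
    fg = data > thr
    if not fg.any():
        raise ValueError("empty foreground after thresholding")
    lab, n = ndi.label(fg, structure=_STRUCT26)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    fg = lab == sizes.argmax()
    fg = ndi.binary_fill_holes(fg, structure=_STRUCT6)
    return fg


def scalp_extract(vol: Volume | np.ndarray, brain: np.ndarray) -> np.ndarray:
    """Head mask: filled largest foreground component, constrained to
    contain the brain reference."""
    if not np.any(brain):
        raise ValueError("empty brain reference")
    H_m = foreground_extract(vol)
    if np.any(brain & ~H_m):
        raise ValueError("brain reference is not contained in the head mask")
    return H_m


# ---------------------------------------------------------------------------
# WM extraction
# ---------------------------------------------------------------------------


def _deepest_component(mask: np.ndarray) -> np.ndarray:
    """The connected component of greatest interior depth (max EDT)."""
    lab, n = ndi.label(mask, structure=_STRUCT26)
    if n <= 1:
        return mask
    edt = ndi.distance_transform_edt(mask)
    best, best_depth = 1, -1.0
    for i in range(1, n + 1):
        d = float(edt[lab == i].max())
        if d > best_depth:
            best, best_depth = i, d
    return lab == best


def wm_extract(wm_raw: np.ndarray) -> np.ndarray:
    """Extract the true WM volume from a raw WM classification.

    The deepest connected component is topology-corrected, surface
    skeletonized, and analyzed as a cell complex; the component of the
    maximum-connectivity center survives a wideness-based bottleneck cut and
    is restored competitively against the discarded skeleton. The result has
    no tunnels or cavities and no bottleneck-attached false positives.
    """
    wm_raw = np.asarray(wm_raw, bool)
    if not wm_raw.any():
        raise ValueError("empty raw WM")
    core = _deepest_component(wm_raw)
    core = tp.topology_correct(core)
    skel = tp.surface_skeletonize(core)
    depth_field = ndi.distance_transform_edt(core)
    cc = ccm.analyze(skel.mask, point_depth=depth_field)
    center = ccm.find_center(cc)
    thr = ccm.otsu_wideness_threshold(cc)
    kept, removed = ccm.partition_by_cores(cc, thr, center, core.shape)
    if removed.any():
        W = ccm.influence_restore(kept, removed, core)
    else:
        W = core
    if not W.any():
        raise ValueError("WM empty after bottleneck cut")
    W = tp.topology_correct(W)
    return W


# ---------------------------------------------------------------------------
# max-flow partition
# ---------------------------------------------------------------------------


def min_cut(mask: np.ndarray, seeds_a: np.ndarray, seeds_b: np.ndarray):
    """s-t minimum cut on the 6-adjacency voxel graph with unit capacities.

    Returns (side_a_mask, side_b_mask, cut_value). The cut value equals the
    maximum flow, certifying minimality.
    """
    mask = np.asarray(mask, bool)
    idx = -np.ones(mask.shape, dtype=np.int64)
    pts = np.argwhere(mask)
    n = len(pts)
    if n == 0:
        raise ValueError("empty mask")
    idx[tuple(pts.T)] = np.arange(n)
    sa = np.unique(idx[np.asarray(seeds_a, bool) & mask])
    sb = np.unique(idx[np.asarray(seeds_b, bool) & mask])
    sa, sb = sa[sa >= 0], sb[sb >= 0]
    if len(sa) == 0 or len(sb) == 0:
        raise ValueError("both seed sets must intersect the mask")
    if np.intersect1d(sa, sb).size:
        raise ValueError("seed sets overlap")
    rows, cols = [], []
    for ax in range(3):
        off = [0, 0, 0]
        off[ax] = 1
        src = tuple(slice(0, s - o) for o, s in zip(off, mask.shape))
        dst = tuple(slice(o, s) for o, s in zip(off, mask.shape))
        both = mask[src] & mask[dst]
        a = idx[src][both]
        b = idx[dst][both]
        rows.extend([a, b])
        cols.extend([b, a])
    S, T = n, n + 1
    big = np.int32(2 ** 28)
    rows = np.concatenate(rows + [np.full(len(sa), S), sa,
                                  sb, np.full(len(sb), T)])
    cols = np.concatenate(cols + [sa, np.full(len(sa), S),
                                  np.full(len(sb), T), sb])
    caps = np.ones(len(rows), dtype=np.int32)
    caps[-(2 * len(sa) + 2 * len(sb)):] = big
    graph = csr_matrix((caps, (rows, cols)), shape=(n + 2, n + 2))
    res = maximum_flow(graph, S, T)
    # reachable set from S in the residual graph
    residual = graph - res.flow
    residual.data = np.maximum(residual.data, 0)
    residual.eliminate_zeros()
    from scipy.sparse.csgraph import breadth_first_order

    order = breadth_first_order(residual, S, directed=True,
                                return_predecessors=False)
    reach = np.zeros(n + 2, dtype=bool)
    reach[order] = True
    side_a = np.zeros(mask.shape, bool)
    side_a[tuple(pts[reach[:n]].T)] = True
    side_b = mask & ~side_a
    return side_a, side_b, int(res.flow_value)


def wm_partition(W: np.ndarray, split_cerebellum: bool = False):
    """Partition WM into left/right (and optionally cerebellar) compartments
    by minimum cut.

    Hemisphere seeds are the deepest voxels near the x-extremes; cerebellar
    seeds come from the inferior-posterior octant. Returns a label volume
    with Tissue.WM_LEFT / WM_RIGHT / WM_CEREBELLAR.
    """
    W = np.asarray(W, bool)
    if not W.any():
        raise ValueError("empty WM")
    out = np.zeros(W.shape, dtype=np.int16)
    body = W
    if split_cerebellum:
        # inferior-posterior octant seeds vs superior seeds
        pts = np.argwhere(W)
        y_mid = np.median(pts[:, 1])
        z_mid = np.median(pts[:, 2])
        inf_post = np.zeros(W.shape, bool)
        inf_post[:, :int(y_mid), :int(z_mid)] = True
        sup = np.zeros(W.shape, bool)
        sup[:, :, int(z_mid) + 2:] = True
        edt = ndi.distance_transform_edt(W)
        qa = np.quantile(edt[W & inf_post], 0.98) if (W & inf_post).any() \
            else np.inf
        qb = np.quantile(edt[W & sup], 0.98) if (W & sup).any() else np.inf
        seeds_c = W & inf_post & (edt >= qa)
        seeds_s = W & sup & (edt >= qb)
        if seeds_c.any() and seeds_s.any():
            cereb, body, _ = min_cut(W, seeds_c, seeds_s)
            out[cereb] = Tissue.WM_CEREBELLAR
        else:
            body = W
    # hemisphere split: the outer-x thirds seed the two sides, so the
    # minimum cut is confined to the central slab (the inter-hemispheric
    # bottleneck when one exists, a near-central disc otherwise)
    pts = np.argwhere(body)
    xs = pts[:, 0]
    x_lo, x_hi = np.quantile(xs, [0.30, 0.70])
    seeds_l = body.copy()
    seeds_r = body.copy()
    seeds_l[int(np.ceil(x_lo)):, :, :] = False
    seeds_r[:int(np.floor(x_hi)) + 1, :, :] = False
    if not seeds_l.any() or not seeds_r.any():
        # degenerate: fall back to single extreme voxels
        seeds_l = np.zeros_like(body)
        seeds_r = np.zeros_like(body)
        seeds_l[tuple(pts[xs.argmin()])] = True
        seeds_r[tuple(pts[xs.argmax()])] = True
    left, right, _ = min_cut(body, seeds_l, seeds_r)
    out[left] = Tissue.WM_LEFT
    out[right] = Tissue.WM_RIGHT
    return out


# ---------------------------------------------------------------------------
# GM extraction
# ---------------------------------------------------------------------------


def gm_extract(rt_labels: np.ndarray, W: np.ndarray, field: np.ndarray,
               d_max: float = 8.0) -> np.ndarray:
    """Keep GM-classified voxels whose gradient path reaches WM within
    ``d_max``; small morphological cleanup."""
    if d_max <= 0:
        return np.zeros(np.asarray(W).shape, bool)
    z = np.asarray(field, dtype=float)
    W = np.asarray(W, bool)
    labels = np.asarray(rt_labels)
    succ = rtmod.successor_field(z)
    is_w = W.ravel()
    start = np.nonzero((labels == Tissue.GM).ravel())[0]
    if len(start) == 0:
        return np.zeros(W.shape, bool)
    keep = is_w[start].copy()  # GM voxel already inside W is trivially close
    for idx, pos, _ in rtmod._walk_masks(z, succ, start, d_max):
        keep[idx] |= is_w[pos]
    G = np.zeros(W.shape, bool)
    G.ravel()[start[keep]] = True
    G &= ~W
    # cleanup: drop tiny speckles
    lab, n = ndi.label(G, structure=_STRUCT26)
    if n > 1:
        sizes = np.bincount(lab.ravel())
        sizes[0] = 0
        G = np.isin(lab, np.nonzero(sizes >= max(8, sizes.max() // 100))[0])
    return G


def inherit_partition(G: np.ndarray, w_partition: np.ndarray) -> np.ndarray:
    """Assign each GM voxel the compartment of the nearest partitioned WM
    voxel; returns labels with Tissue.GM_LEFT / GM_RIGHT / GM_CEREBELLAR."""
    G = np.asarray(G, bool)
    out = np.zeros(G.shape, dtype=np.int16)
    wm_mask = w_partition > 0
    if not wm_mask.any():
        out[G] = Tissue.GM
        return out
    ind = ndi.distance_transform_edt(~wm_mask, return_indices=True)[1]
    nearest = w_partition[tuple(ind)]
    mapping = {Tissue.WM_LEFT: Tissue.GM_LEFT,
               Tissue.WM_RIGHT: Tissue.GM_RIGHT,
               Tissue.WM_CEREBELLAR: Tissue.GM_CEREBELLAR}
    for wcode, gcode in mapping.items():
        out[G & (nearest == wcode)] = gcode
    return out


# ---------------------------------------------------------------------------
# eyeballs
# ---------------------------------------------------------------------------


def eyeball_extract(H_m: np.ndarray, vol: Volume | np.ndarray,
                    brain: np.ndarray | None = None,
                    radii=(4, 5, 6)):
    """Detect two quasi-spherical eyeballs in the anterior part of the head.

    A matched sphere filter runs on the intensity deviation from the local
    head-tissue median, inside an anterior search box. Returns (E1, E2) or
    (None, None) when fewer than two convincing candidates exist.
    """
    data = vol.data if isinstance(vol, Volume) else np.asarray(vol, float)
    H_m = np.asarray(H_m, bool)
    if not H_m.any():
        raise ValueError("empty head mask")
    search = H_m.copy()
    if brain is not None:
        search &= ~ndi.binary_dilation(np.asarray(brain, bool),
                                       iterations=2)
    ys = np.argwhere(H_m)[:, 1]
    y_cut = np.quantile(ys, 0.70)  # anterior 30 % of the head
    search[:, :int(y_cut), :] = False
    if not search.any():
        return None, None
    # quantize the non-brain intensities into a few classes; an eyeball is
    # a compact quasi-spherical component of one class, unlike the shell-
    # shaped bone/CSF/flesh layers
    # sliding intensity windows: an eyeball is a compact quasi-spherical
    # component of near-constant intensity distinct from the layered
    # shells around it (which are thin and far from spherical)
    vals = data[search]
    lo, hi = np.quantile(vals, [0.02, 0.98])
    delta = 0.12 * max(hi - lo, 1e-9)
    candidates = []
    r_lo, r_hi = min(radii) - 1.5, max(radii) + 2.5
    for v in np.quantile(vals, np.linspace(0.05, 0.95, 15)):
        m0 = search & (np.abs(data - v) <= delta)
        m0 = ndi.binary_closing(m0, structure=_STRUCT6)
        lab, n = ndi.label(m0, structure=_STRUCT26)
        for i in range(1, n + 1):
            m = lab == i
            V = int(m.sum())
            r_eq = (3 * V / (4 * np.pi)) ** (1 / 3)
            if not (r_lo <= r_eq <= r_hi):
                continue
            depth = float(ndi.distance_transform_edt(m).max())
            roundness = depth / r_eq
            if roundness >= 0.6:
                candidates.append((roundness, V, m))
    candidates.sort(key=lambda c: (-c[0], -c[1]))
    # best disjoint pair of similar volume
    for i in range(len(candidates)):
        for j in range(i + 1, len(candidates)):
            a, b = candidates[i], candidates[j]
            if max(a[1], b[1]) > 3 * min(a[1], b[1]):
                continue
            if not np.any(a[2] & b[2]):
                return a[2], b[2]
    return None, None


# ---------------------------------------------------------------------------
# CT segmentation
# ---------------------------------------------------------------------------


def ct_segment(ct: Volume, bone_hu: float = 300.0, bg_hu: float = -200.0):
    """Threshold a CT into bone/flesh/background, then split brain from the
    remaining soft tissue with a minimum cut.

    Returns (LabelVolume, density) where density retains the original
    Hounsfield values on bone voxels (NaN elsewhere).
    """
    data = np.asarray(ct.data, float)
    bone = data >= bone_hu
    bg = data <= bg_hu
    flesh = ~bone & ~bg
    if not bone.any():
        raise ValueError("no bone shell found in CT")
    # morphological smoothing of the bone shell
    bone = ndi.binary_closing(bone, structure=_STRUCT6)
    flesh &= ~bone
    labels = np.zeros(data.shape, dtype=np.int16)
    labels[flesh] = Tissue.FLESH
    labels[bone] = Tissue.BONE
    # brain: soft tissue inside the cranial cavity, separated by min cut
    blockers = bone | bg
    cavity_depth = ndi.distance_transform_edt(~blockers)
    inside = flesh & (cavity_depth >= max(2.0,
                                          0.5 * cavity_depth[flesh].max()))
    if inside.any():
        lab, n = ndi.label(inside, structure=_STRUCT26)
        sizes = np.bincount(lab.ravel())
        sizes[0] = 0
        seed_brain = lab == sizes.argmax()
        border = np.zeros(data.shape, bool)
        border[0, :, :] = border[-1, :, :] = True
        border[:, 0, :] = border[:, -1, :] = True
        border[:, :, 0] = border[:, :, -1] = True
        outer = flesh & ndi.binary_dilation(border | bg, iterations=2) \
            & ~seed_brain
        if outer.any():
            brain_side, _, _ = min_cut(flesh, seed_brain, outer)
        else:
            brain_side = ndi.binary_propagation(
                seed_brain, structure=_STRUCT26, mask=flesh)
        labels[brain_side] = Tissue.CSF  # brain compartment in CT terms
    density = np.where(bone, data, np.nan)
    return LabelVolume(labels, ct.spacing, ct.origin), density


# ---------------------------------------------------------------------------
# head-model assembly
# ---------------------------------------------------------------------------


def assemble_head_model(state: CascadeState,
                        skull: np.ndarray | None = None,
                        spacing=(1.0, 1.0, 1.0)):
    """Compose the final exhaustive, exclusive label volume.

    Priority WM > GM > eyeball > bone > CSF > flesh resolves overlaps; CSF
    is redefined as the closed brain region minus WM and GM; in-head voxels
    claimed by nothing become flesh. Returns (HeadModel labels, csf_gap_ok).
    """
    shape = state.H_m.shape
    out = np.zeros(shape, dtype=np.int16)
    wm = state.partition if state.partition is not None else None
    W = state.W2 if state.W2 is not None else state.W1
    G = state.G2 if state.G2 is not None else state.G1
    # brain region: morphological closing of W u G defines the CSF envelope
    brain = ndi.binary_closing(W | G, structure=_STRUCT26, iterations=2)
    csf = ndi.binary_dilation(brain, structure=_STRUCT6) & ~(W | G)
    out[state.H_m] = Tissue.FLESH
    if skull is not None:
        out[skull & state.H_m] = Tissue.BONE
    out[csf & state.H_m] = Tissue.CSF
    for E in (state.E1, state.E2):
        if E is not None:
            out[E & (out != Tissue.WM) & state.H_m] = Tissue.EYEBALL
    if wm is not None and (wm > 0).any():
        gm_part = inherit_partition(G, wm)
        out[G] = np.where(gm_part[G] > 0, gm_part[G], Tissue.GM)
        out[W] = np.where(wm[W] > 0, wm[W], Tissue.WM)
    else:
        out[G] = Tissue.GM
        out[W] = Tissue.WM
    csf_gap_ok = _csf_gap_check(out)
    return LabelVolume(out, spacing), csf_gap_ok


def _csf_gap_check(labels: np.ndarray) -> bool:
    """At least one voxel of CSF between outer GM and inner bone: no GM
    voxel may touch a bone voxel by 6-adjacency."""
    gm = np.isin(labels, Tissue.GM_ALL)
    bone = labels == Tissue.BONE
    if not bone.any():
        return True
    touching = ndi.binary_dilation(gm, structure=_STRUCT6) & bone
    return not touching.any()


# ---------------------------------------------------------------------------
# full cascade
# ---------------------------------------------------------------------------


def run_cascade(vol: Volume, config: CascadeConfig | None = None
                ) -> CascadeState:
    """Run the MRI segmentation cascade on a T1-weighted volume."""
    config = config or CascadeConfig()
    state = CascadeState()
    data = np.asarray(vol.data, float)
    state.R1 = np.ones(data.shape, bool)
    state.R2 = foreground_extract(vol)
    z = rtmod.smooth(data, config.rt.smooth_sigma)
    (t_gw, t_cw), labels1, _ = rtmod.optimize_thresholds(
        z, state.R2, config.rt)
    state.thresholds = (t_gw, t_cw)
    state.rt_labels = labels1
    state.W1 = wm_extract(labels1 == Tissue.WM)
    state.G1 = gm_extract(labels1, state.W1, z, config.gm_d_max)
    # refinement on R3 with the seeded-dilation scheme
    state.R3 = state.W1 | state.G1
    min_card = max(1, int(config.rt.min_card_frac * state.R3.sum()))
    W0, _ = rtmod.seed_wm_by_threshold(z, state.R3, min_card)
    labels2 = rtmod.rt_dilate(z, state.R3, W0, t_gw, config.rt.ref_radius)
    state.W2 = wm_extract(labels2 == Tissue.WM)
    state.partition = wm_partition(state.W2, config.split_cerebellum)
    # G2 against the refined WM, using the scheme-1 GM/CSF classification
    state.G2 = gm_extract(labels1, state.W2, z, config.gm_d_max)
    brain = state.W2 | state.G2
    state.H_m = scalp_extract(vol, brain)
    if config.detect_eyeballs:
        state.E1, state.E2 = eyeball_extract(
            state.H_m, vol, brain, config.eyeball_radii)
    state.check_invariants()
    return state
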