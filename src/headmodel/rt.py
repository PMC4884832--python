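"""Relative thresholding (RT): bias-robust WM/GM/CSF classification.

RT compares each voxel's smoothed intensity with that of a reference voxel
on its *gradient path* — the steepest-ascent chain through 26-neighbors —
against global relative thresholds. Because both voxels sit close together
on the path, a slowly varying multiplicative bias field cancels in the
ratio, so no explicit inhomogeneity correction is needed.

Scheme 1 (t_gw, t_cw exhaustive search):
  * every ROI voxel starts as WM;
  * a voxel becomes GM if some path voxel within distance d_gw is brighter
    than it by more than the factor 1/t_gw (ratio z_i/z_j < t_gw);
  * a GM voxel becomes CSF if some WM path voxel within d_cw (> d_gw)
    satisfies z_i/z_k < t_cw (t_cw < t_gw).
  The (t_gw, t_cw) pair minimizing the intra-class inhomogeneity objective
  h = w_w*h_w + w_g*h_g + w_c*h_c is chosen by exhaustive search, where h_t
  sums |z_i - z_j| over adjacent same-label pairs.

Scheme 2 (seeded dilation): an absolute threshold maximizing the boundary
contrast objective f = f_e - f_r seeds a WM set W0, which is grown by
comparing each frontier voxel with the mean intensity of nearby WM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy import ndimage as ndi

from .phantom import Tissue, Volume

# 26-neighborhood offsets in lexicographic order (ties in the ascent
# direction resolve to the first offset in this order)
_OFFSETS = np.array(
    [(dx, dy, dz)
     for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
     if (dx, dy, dz) != (0, 0, 0)],
    dtype=np.int64,
)
_STEPLEN = np.linalg.norm(_OFFSETS, axis=1)


@dataclass
class RTParams:
    """Search grids and distances for the relative-threshold optimization."""

    t_gw_grid: tuple = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))
    t_cw_grid: tuple = tuple(np.round(np.arange(0.20, 0.51, 0.05), 2))
    # distance thresholds must exceed the cortical thickness so that deep
    # GM voxels reach a WM reference along their gradient path
    d_gw: float = 6.0
    d_cw: float = 12.0
    weights: tuple = (1.0, 1.0, 1.0)
    smooth_sigma: float = 1.0
    min_card_frac: float = 0.01  # minimal |W0| as a fraction of the ROI
    ref_radius: int = 3          # scheme-2 local WM reference radius

    def __post_init__(self) -> None:
        if not (0 < self.d_gw < self.d_cw):
            raise ValueError("need 0 < d_gw < d_cw")
        if any(w < 0 for w in self.weights) or not any(self.weights):
            raise ValueError("weights must be >= 0 and not all zero")


def smooth(vol: Volume | np.ndarray, radius: float = 1.0) -> np.ndarray:
    """Gaussian smoothing (sigma = radius voxels); radius 0 is the identity."""
    data = vol.data if isinstance(vol, Volume) else np.asarray(vol, float)
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if radius == 0:
        return np.asarray(data, dtype=float).copy()
    return ndi.gaussian_filter(np.asarray(data, dtype=float), sigma=radius)


# ---------------------------------------------------------------------------
# gradient paths
# ---------------------------------------------------------------------------


def successor_field(z: np.ndarray) -> np.ndarray:
    """Flat index of the steepest-ascent 26-neighbor per voxel (self at a
    local maximum).

    Ascent steepness is the intensity gain per unit step length, so an
    axis step beats a diagonal one with the same raw gain (the discrete
    analogue of following the gradient direction); remaining ties resolve
    to the lexicographically first offset.
    """
    z = np.asarray(z, dtype=float)
    shape = z.shape
    flat = np.arange(z.size).reshape(shape)
    best_gain = np.zeros(shape)
    best_idx = flat.copy()
    for off, ln in zip(_OFFSETS, _STEPLEN):
        zsh = np.full(shape, -np.inf)
        src = tuple(
            slice(max(0, -o), min(s, s - o)) for o, s in zip(off, shape)
        )
        dst = tuple(
            slice(max(0, o), min(s, s + o)) for o, s in zip(off, shape)
        )
        zsh[src] = z[dst]
        gain = (zsh - z) / ln
        better = gain > best_gain * (1 + 1e-12) + 1e-15
        best_gain = np.where(better, gain, best_gain)
        idxsh = np.full(shape, -1, dtype=np.int64)
        idxsh[src] = flat[dst]
        best_idx = np.where(better, idxsh, best_idx)
    return best_idx.ravel()


def trace_gradient_path(field: np.ndarray, start, max_len: int = 100):
    """Ordered voxel list of the steepest-ascent path from ``start`` and the
    cumulative Euclidean step lengths (voxel units)."""
    z = np.asarray(field, dtype=float)
    succ = successor_field(z)
    shape = z.shape
    cur = int(np.ravel_multi_index(tuple(start), shape))
    path = [np.unravel_index(cur, shape)]
    dists = [0.0]
    for _ in range(max_len - 1):
        nxt = int(succ[cur])
        if nxt == cur:
            break
        p0 = np.asarray(np.unravel_index(cur, shape))
        p1 = np.asarray(np.unravel_index(nxt, shape))
        dists.append(dists[-1] + float(np.linalg.norm(p1 - p0)))
        path.append(tuple(p1))
        cur = nxt
    return path, dists


def _walk_masks(z: np.ndarray, succ: np.ndarray, start_idx: np.ndarray,
                max_dist: float):
    """Generator of (walker_index, position, cumulative_distance) arrays for
    simultaneous steepest-ascent walks from ``start_idx`` (flat indices)."""
    shape = z.shape
    cur = start_idx.copy()
    dist = np.zeros(len(cur))
    active = np.arange(len(cur))
    while len(active) > 0:
        nxt = succ[cur[active]]
        moved = nxt != cur[active]
        active = active[moved]
        if len(active) == 0:
            break
        nxt = nxt[moved]
        p0 = np.column_stack(np.unravel_index(cur[active], shape))
        p1 = np.column_stack(np.unravel_index(nxt, shape))
        dist[active] += np.linalg.norm(p1 - p0, axis=1)
        cur[active] = nxt
        within = dist[active] < max_dist  # spec: path distance strictly less
        active = active[within]
        if len(active):
            yield active, cur[active], dist[active]


def gm_wm_differentiate(field: np.ndarray, roi: np.ndarray, t_gw: float,
                        d_gw: float) -> np.ndarray:
    """Label ROI voxels (initialized WM) as GM where a brighter reference on
    the gradient path within d_gw makes the ratio drop below t_gw.

    Returns an int array with Tissue.WM / Tissue.GM inside the ROI and
    Tissue.BACKGROUND outside.
    """
    if not (0 < t_gw < 1):
        raise ValueError("t_gw must lie in (0, 1)")
    z = np.asarray(field, dtype=float)
    roi = np.asarray(roi, bool)
    succ = successor_field(z)
    zf = z.ravel()
    start = np.nonzero(roi.ravel())[0]
    z0 = zf[start]
    labels = np.full(z.shape, Tissue.BACKGROUND, dtype=np.int16)
    labels[roi] = Tissue.WM
    gm = np.zeros(len(start), dtype=bool)
    for idx, pos, _ in _walk_masks(z, succ, start, d_gw):
        ratio = z0[idx] / np.maximum(zf[pos], 1e-12)
        gm[idx] |= ratio < t_gw
    lab_flat = labels.ravel()
    lab_flat[start[gm]] = Tissue.GM
    return lab_flat.reshape(z.shape)


def csf_gm_differentiate(field: np.ndarray, labels: np.ndarray, t_cw: float,
                         d_cw: float, t_gw: float | None = None,
                         wm_labels=(Tissue.WM,)) -> np.ndarray:
    """Relabel GM voxels as CSF where a WM reference voxel on the gradient
    path within d_cw yields a ratio below t_cw."""
    if t_gw is not None and not (0 < t_cw < t_gw):
        raise ValueError("need 0 < t_cw < t_gw")
    z = np.asarray(field, dtype=float)
    labels = np.asarray(labels).copy()
    succ = successor_field(z)
    zf = z.ravel()
    lab_flat = labels.ravel()
    is_wm = np.isin(lab_flat, wm_labels)
    start = np.nonzero(lab_flat == Tissue.GM)[0]
    if len(start) == 0:
        return labels
    z0 = zf[start]
    csf = np.zeros(len(start), dtype=bool)
    for idx, pos, _ in _walk_masks(z, succ, start, d_cw):
        hit = is_wm[pos]
        ratio = z0[idx] / np.maximum(zf[pos], 1e-12)
        csf[idx] |= hit & (ratio < t_cw)
    lab_flat[start[csf]] = Tissue.CSF
    return lab_flat.reshape(labels.shape)


# ---------------------------------------------------------------------------
# objective and exhaustive search
# ---------------------------------------------------------------------------


def rt_objective(field: np.ndarray, labels: np.ndarray,
                 weights=(1.0, 1.0, 1.0), connectivity: int = 6):
    """Intra-class inhomogeneity h = w_w*h_w + w_g*h_g + w_c*h_c.

    Each class term sums |z_i - z_j| over adjacent voxel pairs that share
    the class label (6-adjacency by default)."""
    z = np.asarray(field, dtype=float)
    labels = np.asarray(labels)
    if connectivity == 6:
        offsets = [(1, 0, 0), (0, 1, 0), (0, 0, 1)]
    else:
        offsets = [tuple(o) for o in _OFFSETS if tuple(o) > (0, 0, 0)]
    terms = {}
    for tissue, name in ((Tissue.WM, "w"), (Tissue.GM, "g"),
                         (Tissue.CSF, "c")):
        total = 0.0
        mask = labels == tissue
        for off in offsets:
            src = tuple(slice(0, s - o) for o, s in zip(off, z.shape))
            dst = tuple(slice(o, s) for o, s in zip(off, z.shape))
            pair = mask[src] & mask[dst]
            total += float(np.abs(z[src][pair] - z[dst][pair]).sum())
        terms[name] = total
    h = (weights[0] * terms["w"] + weights[1] * terms["g"]
         + weights[2] * terms["c"])
    return h, terms["w"], terms["g"], terms["c"]


def class_scatter(field: np.ndarray, labels: np.ndarray,
                  weights=(1.0, 1.0, 1.0)) -> float:
    """Within-object intensity scatter of the three classes.

    Each class is split into its 26-connected components (the class
    *objects*: e.g. scalp flesh and true WM may legitimately share the WM
    label while being distinct objects); every component contributes the
    squared deviation of its member intensities from the component mean.
    """
    z = np.asarray(field, dtype=float)
    struct = np.ones((3, 3, 3), bool)
    total = 0.0
    for w, tissue in zip(weights, (Tissue.WM, Tissue.GM, Tissue.CSF)):
        mask = labels == tissue
        if not mask.any():
            continue
        lab, n = ndi.label(mask, structure=struct)
        flat = lab.ravel()
        vals = z.ravel()
        cnt = np.bincount(flat, minlength=n + 1).astype(float)
        s1 = np.bincount(flat, weights=vals, minlength=n + 1)
        s2 = np.bincount(flat, weights=vals * vals, minlength=n + 1)
        cnt[0] = 1.0  # background bin; contributes nothing below
        scatter = s2[1:] - s1[1:] ** 2 / np.maximum(cnt[1:], 1.0)
        total += w * float(scatter.sum())
    return total


def optimize_thresholds(field: np.ndarray, roi: np.ndarray,
                        params: RTParams, criterion: str = "scatter"):
    """Exhaustive search over the Cartesian product of candidate threshold
    pairs; returns ((t_gw*, t_cw*), labels*, objective*).

    ``criterion`` selects the homogeneity objective: ``"scatter"`` (default)
    ranks pairs by within-class intensity scatter; ``"pair_sum"`` uses the
    adjacent-pair difference sum of :func:`rt_objective`. The pair-sum
    criterion is algebraically a cross-class boundary-contrast maximization
    (same-class and cross-class differences sum to a constant), which on
    piecewise-constant fields favors ragged cuts through the steepest part
    of the boundary blur; the scatter criterion has no such degeneracy.
    """
    pairs = [(tg, tc) for tg, tc in product(params.t_gw_grid,
                                            params.t_cw_grid) if tc < tg]
    if not pairs:
        raise ValueError("no candidate pair satisfies t_cw < t_gw")
    z = np.asarray(field, dtype=float)
    roi = np.asarray(roi, bool)
    # shared path tables: both differentiation passes only need, per ROI
    # voxel, the path positions/distances and the running intensity ratios;
    # these are threshold-independent, so the exhaustive search evaluates
    # each candidate pair with a handful of vectorized comparisons. The
    # result is identical to running the two differentiation passes.
    succ = successor_field(z)
    ids = np.nonzero(roi.ravel())[0]
    zf = z.ravel()
    z0 = zf[ids]
    K = int(np.ceil(params.d_cw)) + 1
    P = np.empty((K + 1, len(ids)), dtype=np.int64)
    D = np.zeros((K + 1, len(ids)), dtype=np.float32)
    P[0] = ids
    shape = z.shape
    for k in range(K):
        nxt = succ[P[k]]
        p0 = np.column_stack(np.unravel_index(P[k], shape))
        p1 = np.column_stack(np.unravel_index(nxt, shape))
        D[k + 1] = D[k] + np.linalg.norm(p1 - p0, axis=1).astype(np.float32)
        D[k + 1][nxt == P[k]] = np.inf  # stationary: no further reference
        P[k + 1] = nxt
    ZP = zf[P[1:]]
    DP = D[1:]
    ratio = z0[None, :] / np.maximum(ZP, 1e-12)
    zmax_gw = np.where(DP < params.d_gw, ZP, -np.inf).max(axis=0)
    R = z0 / np.maximum(np.maximum(zmax_gw, z0), 1e-12)
    Rvol = np.full(z.size, -1.0)
    Rvol[ids] = R
    RP = Rvol[P[1:]]

    best = None
    for t_gw, t_cw in pairs:
        gm = R < t_gw
        csf_hit = ((DP < params.d_cw) & (RP >= t_gw)
                   & (ratio < t_cw)).any(axis=0)
        csf = gm & csf_hit
        labels = np.full(z.shape, Tissue.BACKGROUND, dtype=np.int16)
        lab_flat = labels.ravel()
        lab_flat[ids] = Tissue.WM
        lab_flat[ids[gm & ~csf]] = Tissue.GM
        lab_flat[ids[csf]] = Tissue.CSF
        labels = lab_flat.reshape(z.shape)
        if criterion == "scatter":
            h = class_scatter(z, labels, params.weights)
        else:
            h, *_ = rt_objective(z, labels, params.weights)
        key = (h, t_gw, t_cw)
        if best is None or key < best[0]:
            best = (key, (t_gw, t_cw), labels)
    return best[1], best[2], best[0][0]


# ---------------------------------------------------------------------------
# scheme 2: seeded dilation
# ---------------------------------------------------------------------------


def seed_wm_by_threshold(field: np.ndarray, roi: np.ndarray,
                         min_card: int, n_levels: int = 64):
    """Absolute threshold maximizing f = f_e - f_r; returns (W0, threshold).

    f_e sums |z_i - z_j| over the m WM/non-WM adjacent pairs inside the ROI;
    f_r sums the m largest |z_i - z_j| among WM-WM adjacent pairs. The
    lowest threshold attains ties; |W0| >= min_card is required.
    """
    z = np.asarray(field, dtype=float)
    roi = np.asarray(roi, bool)
    if not roi.any():
        raise ValueError("empty ROI")
    vals = z[roi]
    levels = np.unique(np.quantile(vals, np.linspace(0.02, 0.98, n_levels)))
    offsets = [(1, 0, 0), (0, 1, 0), (0, 0, 1)]
    # precompute adjacent in-ROI pairs once
    pairs = []
    for off in offsets:
        src = tuple(slice(0, s - o) for o, s in zip(off, z.shape))
        dst = tuple(slice(o, s) for o, s in zip(off, z.shape))
        both = roi[src] & roi[dst]
        pairs.append((z[src][both], z[dst][both]))
    za = np.concatenate([p[0] for p in pairs])
    zb = np.concatenate([p[1] for p in pairs])
    dz = np.abs(za - zb)
    best = None
    for t in levels:
        w = vals >= t
        if int(w.sum()) < min_card:
            continue
        wa = za >= t
        wb = zb >= t
        cross = wa != wb
        m = int(cross.sum())
        f_e = float(dz[cross].sum())
        ww = wa & wb
        dww = dz[ww]
        if m > 0 and len(dww) > 0:
            k = min(m, len(dww))
            f_r = float(np.partition(dww, len(dww) - k)[len(dww) - k:].sum())
        else:
            f_r = 0.0
        f = f_e - f_r
        key = (-f, t)
        if best is None or key < best[0]:
            best = (key, t)
    if best is None:
        raise ValueError(
            f"no threshold yields at least {min_card} seed voxels"
        )
    t = best[1]
    W0 = roi & (z >= t)
    return W0, float(t)


def rt_dilate(field: np.ndarray, roi: np.ndarray, W0: np.ndarray,
              t_gw: float, ref_radius: int = 3) -> np.ndarray:
    """Grow W0 inside the ROI: a frontier voxel joins WM when its intensity
    is at least t_gw times the reference intensity of WM voxels within
    ``ref_radius``; iterate to fixpoint. Remaining ROI voxels become GM.

    The reference is the local WM intensity maximum: it tracks the bias
    field like a local mean but cannot be dragged down by dim voxels joined
    at the frontier, which would otherwise let the dilation run away into
    GM once the accepted boundary shell lowers a mean-based reference.
    """
    z = np.asarray(field, dtype=float)
    roi = np.asarray(roi, bool)
    W = np.asarray(W0, bool).copy()
    if not W.any():
        raise ValueError("empty WM seed set")
    if np.any(W & ~roi):
        raise ValueError("W0 must lie inside the ROI")
    size = 2 * ref_radius + 1
    struct = np.ones((3, 3, 3), bool)
    while True:
        ref = ndi.maximum_filter(np.where(W, z, -np.inf), size)
        frontier = ndi.binary_dilation(W, struct) & roi & ~W
        join = frontier & np.isfinite(ref) & (z >= t_gw * ref)
        if not join.any():
            break
        W |= join
    labels = np.full(z.shape, Tissue.BACKGROUND, dtype=np.int16)
    labels[roi] = Tissue.GM
    labels[W] = Tissue.WM
    return labels
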