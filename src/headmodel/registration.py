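"""Landmark-driven rigid, affine and thin-plate-spline registration.

All similarity measures are sums of squared distances from transformed
landmarks to a target contour, evaluated through a precomputed Euclidean
distance field (equivalent to nearest-point search, but deterministic and
cheap). Rigid coefficients come from a multiscale exhaustive grid search,
affine coefficients from gradient descent initialized at the rigid optimum,
and local deformation from a thin-plate spline (TPS) with kernel
U(r) = r^2 ln r^2 solved exactly from the landmark correspondences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

_STRUCT6 = ndi.generate_binary_structure(3, 1)


@dataclass
class LandmarkSet:
    """Named 3D points with role tags."""

    points: np.ndarray                      # (n, 3)
    names: list[str] | None = None
    roles: list[str] | None = None          # inferior/superior/mate/...

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, float))
        if not np.all(np.isfinite(self.points)):
            raise ValueError("landmark coordinates must be finite")


@dataclass
class LinearTransform:
    """Rigid or affine map as a 3x4 matrix [A | t]."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, float).reshape(3, 4)

    @property
    def A(self) -> np.ndarray:
        return self.matrix[:, :3]

    @property
    def t(self) -> np.ndarray:
        return self.matrix[:, 3]

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, float))
        return pts @ self.A.T + self.t

    def compose(self, other: "LinearTransform") -> "LinearTransform":
        """self o other (apply ``other`` first)."""
        A = self.A @ other.A
        t = self.A @ other.t + self.t
        return LinearTransform(np.column_stack([A, t]))

    def inverse(self) -> "LinearTransform":
        Ainv = np.linalg.inv(self.A)
        return LinearTransform(np.column_stack([Ainv, -Ainv @ self.t]))

    @staticmethod
    def identity() -> "LinearTransform":
        return LinearTransform(np.column_stack([np.eye(3), np.zeros(3)]))

    def is_rigid(self, tol: float = 1e-6) -> bool:
        R = self.A
        return (np.allclose(R @ R.T, np.eye(3), atol=tol)
                and np.linalg.det(R) > 0)


# ---------------------------------------------------------------------------
# distance fields
# ---------------------------------------------------------------------------


def contour(mask: np.ndarray) -> np.ndarray:
    """Boundary voxels of a mask (mask minus its 6-erosion)."""
    mask = np.asarray(mask, bool)
    return mask & ~ndi.binary_erosion(mask, structure=_STRUCT6,
                                      border_value=0)


def distance_field(mask: np.ndarray) -> np.ndarray:
    """Euclidean distance to the mask contour (zero on contour voxels)."""
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask has no contour")
    c = contour(mask)
    return ndi.distance_transform_edt(~c)


def _sample_sq(dist2: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Interpolated values of a squared distance field at (fractional)
    points.

    The squared field is smooth across the contour (the distance itself has
    a kink there); points outside the grid are clamped, with the
    out-of-grid excess added."""
    pts = np.atleast_2d(pts)
    coords = [np.clip(pts[:, i], 0, dist2.shape[i] - 1) for i in range(3)]
    over = np.zeros(len(pts))
    for i in range(3):
        over += np.maximum(pts[:, i] - (dist2.shape[i] - 1), 0) ** 2
        over += np.maximum(-pts[:, i], 0) ** 2
    return ndi.map_coordinates(dist2, coords, order=1) + over


def landmark_cost(dist: np.ndarray, pts: np.ndarray) -> float:
    """Sum of squared distances from the points to the contour."""
    return float(_sample_sq(dist * dist, pts).sum())


# ---------------------------------------------------------------------------
# rigid: multiscale exhaustive search
# ---------------------------------------------------------------------------


def _euler_matrix(ax: float, ay: float, az: float) -> np.ndarray:
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def rigid_fit(landmarks: np.ndarray, target_mask: np.ndarray,
              t_range: float = 20.0, a_range: float = 20.0,
              levels: int = 3, dist: np.ndarray | None = None
              ) -> LinearTransform:
    """Multiscale exhaustive search for the rigid transform minimizing the
    sum of squared landmark-to-contour distances.

    Rotation is about the landmark centroid; translation within
    ``t_range`` voxels, rotation within ``a_range`` degrees, refined over
    ``levels`` grid levels (final steps: 1 voxel, 1.5 degrees; the grid
    optimum is returned).
    """
    pts = np.atleast_2d(np.asarray(landmarks, float))
    if len(pts) < 3:
        raise ValueError("need at least 3 landmarks")
    if dist is None:
        dist = distance_field(target_mask)
    dist2 = dist * dist
    centroid = pts.mean(axis=0)
    local = pts - centroid

    t_best = np.zeros(3)
    a_best = np.zeros(3)
    t_step, a_step = t_range / 2.5, a_range / 2.0
    t_span, a_span = t_range, a_range
    for level in range(levels):
        kt = int(np.ceil(t_span / t_step))
        ka = int(np.ceil(a_span / a_step))
        t_vals = [c + t_step * np.arange(-kt, kt + 1) for c in t_best]
        a_vals = [c + a_step * np.arange(-ka, ka + 1) for c in a_best]
        trans = np.stack(np.meshgrid(*t_vals, indexing="ij"),
                         axis=-1).reshape(-1, 3)
        best = None
        for aX in a_vals[0]:
            for aY in a_vals[1]:
                for aZ in a_vals[2]:
                    R = _euler_matrix(*np.deg2rad([aX, aY, aZ]))
                    rot = local @ R.T + centroid
                    allpts = rot[None, :, :] + trans[:, None, :]
                    costs = _sample_sq(
                        dist2, allpts.reshape(-1, 3)
                    ).reshape(len(trans), -1).sum(axis=1)
                    # near-ties resolve to the smallest motion (symmetric
                    # targets leave rotations unconstrained otherwise)
                    mag = (trans ** 2).sum(axis=1)
                    k = int(np.lexsort((mag, np.round(costs, 6)))[0])
                    key = (round(costs[k], 6),
                           aX * aX + aY * aY + aZ * aZ, mag[k],
                           aX, aY, aZ, *trans[k])
                    if best is None or key < best:
                        best = key
        a_best = np.array(best[3:6])
        t_best = np.array(best[6:9])
        t_span, t_step = t_step, max(t_step / 3.0, 1.0)
        a_span, a_step = a_step, max(a_step / 3.0, 1.5)
    R = _euler_matrix(*np.deg2rad(a_best))
    t = t_best + centroid - R @ centroid
    return LinearTransform(np.column_stack([R, t]))


# ---------------------------------------------------------------------------
# affine: gradient descent
# ---------------------------------------------------------------------------


def affine_fit(landmarks: np.ndarray, target_mask: np.ndarray,
               init: LinearTransform, max_iter: int = 200,
               dist: np.ndarray | None = None) -> LinearTransform:
    """Local gradient descent on the 12 affine parameters.

    The objective (mean squared landmark-to-contour distance) is
    non-increasing over accepted steps; step halving on failure, stopping
    after ``max_iter`` iterations or when no progress is possible.
    """
    pts = np.atleast_2d(np.asarray(landmarks, float))
    if dist is None:
        dist = distance_field(target_mask)
    dist2 = dist * dist
    centroid = pts.mean(axis=0)
    local = pts - centroid
    # normalized coordinates make all 12 parameter sensitivities comparable
    scale = float(np.sqrt((local ** 2).sum(axis=1).mean())) or 1.0
    local_n = local / scale

    def unpack(p):
        return p[:9].reshape(3, 3), p[9:]

    def cost(p):
        A, t = unpack(p)
        moved = local_n @ A.T * scale + centroid + t
        return float(_sample_sq(dist2, moved).mean())

    # initialize from the rigid result, re-expressed about the centroid
    from scipy.optimize import minimize

    def descend(p):
        f = cost(p)
        lr = 0.02
        eps = 1e-4
        for _ in range(min(max_iter, 60)):
            grad = np.zeros(12)
            for i in range(12):
                dp = np.zeros(12)
                dp[i] = eps
                grad[i] = (cost(p + dp) - cost(p - dp)) / (2 * eps)
            norm = np.linalg.norm(grad)
            if norm < 1e-10:
                break
            step = lr * grad / norm
            improved = False
            for _ in range(15):  # step halving
                ft = cost(p - step)
                if ft < f - 1e-12:
                    p, f = p - step, ft
                    improved = True
                    lr = min(lr * 1.5, 1.0)
                    break
                step = step / 2
                lr = max(lr / 2, 1e-5)
            if not improved:
                break
        # line-search polish: the numeric-gradient descent stalls on the
        # interpolation lattice when parameters mostly slide points along
        # the contour surface; Powell's line searches escape those plateaus
        # while keeping the objective non-increasing
        res = minimize(cost, p, method="Powell",
                       options=dict(maxiter=max_iter * 20, xtol=1e-6,
                                    ftol=1e-12))
        return (res.x, res.fun) if res.fun <= f else (p, f)

    starts = [np.concatenate([init.A.ravel(),
                              init.apply(centroid[None])[0] - centroid])]
    ident = np.concatenate([np.eye(3).ravel(), np.zeros(3)])
    if not np.allclose(starts[0], ident):
        starts.append(ident)  # guards against a spurious rigid rotation
    p, f = descend(starts[0])
    if f > 1e-6 and len(starts) > 1:
        p2, f2 = descend(starts[1])
        if f2 < f:
            p, f = p2, f2
    A, t = unpack(p)
    tt = t + centroid - A @ centroid
    return LinearTransform(np.column_stack([A, tt]))


# ---------------------------------------------------------------------------
# thin-plate spline
# ---------------------------------------------------------------------------


def _tps_kernel(r2: np.ndarray) -> np.ndarray:
    """U(r) = r^2 ln r^2, with the removable singularity U(0) = 0."""
    out = np.zeros_like(r2)
    pos = r2 > 0
    out[pos] = r2[pos] * np.log(r2[pos])
    return out


@dataclass
class TPSTransform:
    """Thin-plate spline map fitted from paired landmarks.

    Coefficients form the (n+4) x 3 matrix W (kernel weights then affine
    rows) solving L W = M for exact interpolation of the landmark pairs.
    """

    sources: np.ndarray
    W: np.ndarray = field(repr=False, default=None)

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, float))
        if len(pts) == 0:
            return pts.reshape(0, 3)
        d = pts[:, None, :] - self.sources[None, :, :]
        U = _tps_kernel((d ** 2).sum(axis=2))
        P = np.column_stack([np.ones(len(pts)), pts])
        return U @ self.W[:-4] + P @ self.W[-4:]

    @property
    def kernel_weights(self) -> np.ndarray:
        return self.W[:-4]

    @property
    def affine_part(self) -> np.ndarray:
        return self.W[-4:]


def tps_fit(source, target) -> TPSTransform:
    """Solve L W = M for the TPS mapping source landmarks onto targets."""
    src = source.points if isinstance(source, LandmarkSet) else \
        np.atleast_2d(np.asarray(source, float))
    dst = target.points if isinstance(target, LandmarkSet) else \
        np.atleast_2d(np.asarray(target, float))
    n = len(src)
    if n < 4:
        raise ValueError("need at least 4 landmarks")
    if src.shape != dst.shape:
        raise ValueError("source/target landmark counts differ")
    d = src[:, None, :] - src[None, :, :]
    K = _tps_kernel((d ** 2).sum(axis=2))
    P = np.column_stack([np.ones(n), src])
    L = np.zeros((n + 4, n + 4))
    L[:n, :n] = K
    L[:n, n:] = P
    L[n:, :n] = P.T
    M = np.zeros((n + 4, 3))
    M[:n] = dst
    try:
        W = np.linalg.solve(L, M)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular TPS system (coincident or coplanar landmarks)"
        ) from exc
    if not np.all(np.isfinite(W)):
        raise ValueError("TPS solve produced non-finite coefficients")
    return TPSTransform(src, W)


def tps_apply(t: TPSTransform, pts: np.ndarray) -> np.ndarray:
    return t.apply(pts)


# ---------------------------------------------------------------------------
# MRI/CT landmark extraction
# ---------------------------------------------------------------------------


def _mask_center(mask: np.ndarray) -> np.ndarray:
    return np.argwhere(mask).mean(axis=0)


def extract_mri_ct_landmarks(B_m, H_m, E1=None, E2=None,
                             max_landmarks: int = 300):
    """Inferior landmarks from the brain-mask border below the reference
    plane; superior landmarks from the head-mask contour above it.

    The plane passes through the brain center and the two eyeball centers;
    without eyeballs (or with collinear centers) an axial plane through the
    brain center is used. Returns (inferior, superior) LandmarkSets.
    """
    B_m = np.asarray(B_m, bool)
    H_m = np.asarray(H_m, bool)
    if not B_m.any() or not H_m.any():
        raise ValueError("empty mask")
    bc = _mask_center(B_m)
    normal = None
    if E1 is not None and E2 is not None and np.any(E1) and np.any(E2):
        c1, c2 = _mask_center(E1), _mask_center(E2)
        v1, v2 = c1 - bc, c2 - bc
        n = np.cross(v1, v2)
        if np.linalg.norm(n) > 1e-6:
            normal = n / np.linalg.norm(n)
            if normal[2] < 0:
                normal = -normal  # superior side has positive z
    if normal is None:
        normal = np.array([0.0, 0.0, 1.0])
    bpts = np.argwhere(contour(B_m))
    hpts = np.argwhere(contour(H_m))
    side_b = (bpts - bc) @ normal
    side_h = (hpts - bc) @ normal
    inf_pts = bpts[side_b <= 0]
    sup_pts = hpts[side_h > 0]
    inf_pts = _subsample(inf_pts, max_landmarks // 2)
    sup_pts = _subsample(sup_pts, max_landmarks // 2)
    return (LandmarkSet(inf_pts, roles=["inferior"] * len(inf_pts)),
            LandmarkSet(sup_pts, roles=["superior"] * len(sup_pts)))


def _subsample(pts: np.ndarray, n_max: int) -> np.ndarray:
    if len(pts) <= n_max:
        return pts
    step = int(np.ceil(len(pts) / n_max))
    order = np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0]))
    return pts[order][::step]


# ---------------------------------------------------------------------------
# ray casting helpers
# ---------------------------------------------------------------------------


def _ray_exit(mask: np.ndarray, origin: np.ndarray, direction: np.ndarray,
              step: float = 0.25, t_max: float | None = None):
    """Outermost point of ``mask`` along the ray origin + t*direction
    (t > 0), or None when the ray never enters the mask."""
    direction = np.asarray(direction, float)
    nrm = np.linalg.norm(direction)
    if nrm < 1e-12:
        return None
    direction = direction / nrm
    if t_max is None:
        t_max = float(np.linalg.norm(mask.shape) + 1)
    ts = np.arange(step, t_max, step)
    pts = origin[None, :] + ts[:, None] * direction[None, :]
    ok = np.all((pts >= 0) & (pts <= np.asarray(mask.shape) - 1), axis=1)
    pts, ts = pts[ok], ts[ok]
    if len(pts) == 0:
        return None
    inside = ndi.map_coordinates(mask.astype(np.float32), pts.T,
                                 order=0) > 0.5
    if not inside.any():
        return None
    return origin + ts[np.nonzero(inside)[0].max()] * direction


# ---------------------------------------------------------------------------
# atlas skull fitting
# ---------------------------------------------------------------------------


@dataclass
class SkullFitParams:
    global_ratio: float
    source_mates: np.ndarray
    target_mates: np.ndarray
    local_ratios: np.ndarray
    frac_outside_brain: float


def atlas_skull_fit(atlas: dict, subject: dict,
                    n_landmarks: int = 120,
                    outside_quantile: float = 0.90):
    """Fit the atlas skull into subject space: rigid -> affine -> TPS.

    ``atlas`` needs boolean masks ``brain``, ``head``, ``skull``;
    ``subject`` needs ``brain`` and ``head``. Superior sources sit on the
    atlas head contour with skull-thickness mate landmarks on the inner
    skull surface; superior targets are scalp intersections of the rays
    from the subject brain center; target mates sit at the global thickness
    ratio (locally reduced so that at least ``outside_quantile`` of them
    fall outside the subject brain mask). Returns (TPSTransform,
    SkullFitParams); the TPS maps original atlas coordinates to subject
    space.
    """
    B_a, H_a, K_a = atlas["brain"], atlas["head"], atlas["skull"]
    B_m, H_m = subject["brain"], subject["head"]
    # rigid + affine: subject brain border vs atlas brain contour, inverted
    dist_a = distance_field(B_a)
    border = _subsample(np.argwhere(contour(B_m)), n_landmarks)
    rig = rigid_fit(border, B_a, dist=dist_a)
    aff = affine_fit(border, B_a, rig, dist=dist_a)
    fwd = aff.inverse()  # atlas -> subject initial alignment

    ac = _mask_center(B_a)
    sc = _mask_center(B_m)
    dist_bm = ndi.distance_transform_edt(~B_m)

    # superior atlas sources on the head contour (above the brain center)
    hpts = np.argwhere(contour(H_a))
    sup = hpts[hpts[:, 2] > ac[2]]
    sup = _subsample(sup, n_landmarks)
    src, dst = [], []
    s_mates, t_mates, d_s = [], [], []
    for s in sup.astype(float):
        # atlas mate: inner skull surface on the segment source -> center
        m = _last_on_segment(K_a, s, ac)
        if m is None:
            continue
        tgt = _ray_exit(H_m, sc, fwd.apply(s[None])[0] - sc)
        if tgt is None:
            continue
        src.append(s)
        dst.append(tgt)
        s_mates.append(m)
        d_s.append(np.linalg.norm(s - m))
    if len(src) < 8:
        raise ValueError("too few superior correspondences for skull fit")
    src, dst = np.array(src), np.array(dst)
    s_mates, d_s = np.array(s_mates), np.array(d_s)

    # global thickness ratio (subject/atlas skull thickness): estimated by
    # how the scalp-to-brain gap scales between atlas and subject, then
    # capped at the largest value keeping the stated share of target mates
    # off the subject brain mask; violators get a local reduction
    dirs = dst - sc
    dirs /= np.linalg.norm(dirs, axis=1)[:, None]
    dirs_a = src - ac
    dirs_a /= np.linalg.norm(dirs_a, axis=1)[:, None]
    r_max = np.empty(len(dst))
    gap_ratio = np.empty(len(dst))
    for i in range(len(dst)):
        r_max[i] = _max_inward_ratio(B_m, dst[i], -dirs[i], d_s[i])
        gap_s = _max_inward_ratio(B_a, src[i], -dirs_a[i], d_s[i])
        gap_ratio[i] = r_max[i] / max(gap_s, 1e-9)
    cap = float(np.quantile(r_max, 1 - outside_quantile))
    ratio = float(min(np.median(gap_ratio), cap))
    if not np.any(r_max > 0):
        raise ValueError("all target mates fall inside the brain mask")
    local = np.minimum(ratio, r_max * 0.98)
    t_mates = dst - dirs * (local * d_s)[:, None]

    # inferior landmarks: brain-mask border below the center
    bpts = np.argwhere(contour(B_a))
    inf_src = _subsample(bpts[bpts[:, 2] <= ac[2]], n_landmarks // 2)
    inf_dst = []
    inf_keep = []
    y_mid = ac[1]
    grad = np.array(np.gradient(dist_bm))
    inf_mate_src, inf_mate_dst = [], []
    for s in inf_src.astype(float):
        p = fwd.apply(s[None])[0]
        if s[1] <= y_mid:  # posterior: ray from the brain center
            tgt = _ray_exit(B_m, sc, p - sc)
            if tgt is not None:
                # posterior mate on the outside of the atlas skull, its
                # target placed by the global thickness ratio
                sm = _ray_exit(K_a, ac, s - ac)
                if sm is not None:
                    out_dir = tgt - sc
                    out_dir = out_dir / np.linalg.norm(out_dir)
                    inf_mate_src.append(sm)
                    inf_mate_dst.append(
                        tgt + out_dir * ratio * np.linalg.norm(sm - s))
        else:              # anterior: descend the brain distance field
            tgt = _descend_to_contour(dist_bm, grad, p)
        if tgt is not None:
            inf_keep.append(s)
            inf_dst.append(tgt)
    blocks_s = [src, s_mates] + ([inf_keep] if inf_keep else []) \
        + ([inf_mate_src] if inf_mate_src else [])
    blocks_t = [dst, t_mates] + ([inf_dst] if inf_dst else []) \
        + ([inf_mate_dst] if inf_mate_dst else [])
    sources = np.vstack(blocks_s)
    targets = np.vstack(blocks_t)
    tps = tps_fit(sources, targets)
    inside = ndi.map_coordinates(B_m.astype(np.float32),
                                 t_mates.T, order=0) > 0.5
    params = SkullFitParams(
        global_ratio=ratio, source_mates=s_mates, target_mates=t_mates,
        local_ratios=local, frac_outside_brain=float(1 - inside.mean()),
    )
    return tps, params


def _last_on_segment(mask, a, b, step: float = 0.25):
    """Last voxel of mask on the segment a -> b (near a's side), or None."""
    d = np.asarray(b, float) - np.asarray(a, float)
    ln = np.linalg.norm(d)
    if ln < 1e-9:
        return None
    ts = np.arange(0, ln, step)
    pts = np.asarray(a)[None] + ts[:, None] * (d / ln)[None]
    ok = np.all((pts >= 0) & (pts <= np.asarray(mask.shape) - 1), axis=1)
    pts, ts = pts[ok], ts[ok]
    inside = ndi.map_coordinates(mask.astype(np.float32), pts.T,
                                 order=0) > 0.5
    if not inside.any():
        return None
    return pts[np.nonzero(inside)[0].max()]


def _max_inward_ratio(B_m, start, direction, d_s, step: float = 0.25):
    """Largest k such that start + k*d_s*direction stays outside B_m."""
    if d_s < 1e-9:
        return 1.0
    ts = np.arange(step, 4 * d_s, step)
    pts = start[None] + ts[:, None] * direction[None]
    ok = np.all((pts >= 0) & (pts <= np.asarray(B_m.shape) - 1), axis=1)
    pts, ts = pts[ok], ts[ok]
    if len(pts) == 0:
        return 4.0
    inside = ndi.map_coordinates(B_m.astype(np.float32), pts.T,
                                 order=0) > 0.5
    if not inside.any():
        return 4.0
    return float(ts[inside].min() / d_s)


def _descend_to_contour(dist, grad, p, n_steps: int = 200):
    """Follow the negative gradient of a contour distance field to the
    contour (distance ~ 0)."""
    p = np.asarray(p, float).copy()
    for _ in range(n_steps):
        ijk = tuple(np.clip(np.round(p).astype(int), 0,
                            np.asarray(dist.shape) - 1))
        if dist[ijk] <= 0.8:
            return p
        g = grad[:, ijk[0], ijk[1], ijk[2]]
        n = np.linalg.norm(g)
        if n < 1e-9:
            return None
        p = p - g / n * 0.5
    return None


# ---------------------------------------------------------------------------
# sensor registrations
# ---------------------------------------------------------------------------


def _procrustes_rigid(src: np.ndarray, dst: np.ndarray) -> LinearTransform:
    """Least-squares rigid alignment of paired points (Kabsch)."""
    src, dst = np.atleast_2d(src), np.atleast_2d(dst)
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    H = (src - cs).T @ (dst - cd)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1, 1, d]) @ U.T
    t = cd - R @ cs
    return LinearTransform(np.column_stack([R, t]))


def sensors_to_head(cloud, H_m: np.ndarray, brain_center=None,
                    fiducials: dict | None = None,
                    head_fiducials: dict | None = None):
    """Map a sensor cloud onto the scalp.

    Generic mode translates the cloud center onto the brain center and
    projects each sensor along the ray from the brain center (the first
    scalp intersection from outside, i.e. the outermost head-mask crossing).
    When paired fiducials are given, a rigid Procrustes alignment replaces
    the translation. Returns (new SensorCloud, per-sensor success mask).
    """
    from .phantom import SensorCloud

    H_m = np.asarray(H_m, bool)
    if not H_m.any():
        raise ValueError("empty head mask")
    if brain_center is None:
        brain_center = _mask_center(H_m)
    brain_center = np.asarray(brain_center, float)
    pts = cloud.points.copy()
    if fiducials and head_fiducials:
        common = sorted(set(fiducials) & set(head_fiducials))
        if len(common) >= 3:
            T = _procrustes_rigid(
                np.array([fiducials[k] for k in common]),
                np.array([head_fiducials[k] for k in common]))
            pts = T.apply(pts)
        else:
            raise ValueError("need >= 3 matched fiducials")
    else:
        pts = pts - pts.mean(axis=0) + brain_center
    out = np.empty_like(pts)
    ok = np.ones(len(pts), dtype=bool)
    for i, p in enumerate(pts):
        d = p - brain_center
        if np.linalg.norm(d) < 1e-9:
            ok[i] = False
            out[i] = p
            continue
        hit = _ray_exit(H_m, brain_center, d)
        if hit is None:
            ok[i] = False
            out[i] = p
        else:
            out[i] = hit
    return SensorCloud(list(cloud.labels), out,
                       dict(cloud.fiducials)), ok


def mri_to_gps(H_m: np.ndarray, brain_center, cloud, mode: str = "auto",
               mri_fiducials: dict | None = None):
    """Deform the head so every sensor lies on the scalp.

    Steps: (1) align the sensor cloud to the scalp (exhaustive rigid search
    in ``auto`` mode; nasion-constrained rigid in ``nasion`` mode; 3-point
    Procrustes in ``3-fiducial`` mode), (2) affine refinement, (3) TPS with
    scalp sources on the rays from the brain center to the aligned sensors
    and the aligned sensors as targets. Returns (TPSTransform, aligned
    sensor positions). Applying the TPS to the scalp realizes the
    deformation; each aligned sensor then lies on the deformed scalp.
    """
    H_m = np.asarray(H_m, bool)
    if len(cloud) < 4:
        raise ValueError("need at least 4 sensors")
    brain_center = np.asarray(brain_center, float)
    dist = distance_field(H_m)
    pts = cloud.points
    already_aligned = float(_sample_sq(dist * dist, pts).mean()) < 1.0
    if mode == "auto":
        if already_aligned:  # nothing for the linear steps to improve
            rig = LinearTransform.identity()
        else:
            rig = rigid_fit(pts, H_m, dist=dist)
    elif mode == "nasion":
        if "nasion" not in cloud.fiducials or not mri_fiducials \
                or "nasion" not in mri_fiducials:
            raise ValueError("nasion mode needs the nasion fiducial on "
                             "both sides")
        shift = np.asarray(mri_fiducials["nasion"]) \
            - np.asarray(cloud.fiducials["nasion"])
        pre = LinearTransform(np.column_stack([np.eye(3), shift]))
        rig0 = rigid_fit(pre.apply(pts), H_m, t_range=2.0, dist=dist)
        rig = rig0.compose(pre)
    elif mode == "3-fiducial":
        need = ("nasion", "periauricular_left", "periauricular_right")
        if not mri_fiducials or any(k not in cloud.fiducials
                                    or k not in mri_fiducials
                                    for k in need):
            raise ValueError("3-fiducial mode needs nasion and both "
                             "periauricular fiducials on both sides")
        rig = _procrustes_rigid(
            np.array([cloud.fiducials[k] for k in need]),
            np.array([mri_fiducials[k] for k in need]))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    aligned = rig.apply(pts)
    if float(_sample_sq(dist * dist, aligned).mean()) >= 1.0:
        aff = affine_fit(aligned, H_m, LinearTransform.identity(),
                         dist=dist)
        aligned = aff.apply(aligned)
    sources, targets = [], []
    for g in aligned:
        s = _ray_exit(H_m, brain_center, g - brain_center)
        if s is not None:
            sources.append(s)
            targets.append(g)
    if len(sources) < 4:
        raise ValueError("too few scalp correspondences")
    tps = tps_fit(np.array(sources), np.array(targets))
    return tps, aligned
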