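"""Cortical surface reconstruction, inflation, dipole tessellation and the
Talairach transform.

Surfaces are extracted with marching cubes from topology-corrected masks
(closed 2-manifold triangle meshes, Euler characteristic 2 per genus-0
component). Dipole tessellation partitions the triangle dual graph into k
edge-connected patches of similar area; each patch carries one equivalent
dipole at its area-weighted centroid, oriented along the area-weighted mean
of the triangle normals. Without an individual surface, unoriented dipole
triples are spread quasi-uniformly through cortical gray matter by
farthest-point sampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from skimage import measure as skmeasure


# ---------------------------------------------------------------------------
# surface extraction and inflation
# ---------------------------------------------------------------------------


def extract_surface(mask: np.ndarray, spacing=(1.0, 1.0, 1.0),
                    smooth_iters: int = 0) -> trimesh.Trimesh:
    """Closed manifold triangle mesh of a binary compartment (marching
    cubes at the 0.5 level on the zero-padded mask)."""
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty compartment")
    padded = np.pad(mask, 1).astype(np.float32)
    verts, faces, _, _ = skmeasure.marching_cubes(
        padded, level=0.5, spacing=spacing)
    verts -= np.asarray(spacing)  # undo the padding offset
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    trimesh.repair.fix_normals(mesh)
    for _ in range(smooth_iters):
        mesh = inflate(mesh, 1, alpha=0.8)
    return mesh


def mesh_euler_characteristic(mesh: trimesh.Trimesh) -> int:
    return int(mesh.euler_number)


def is_closed_manifold(mesh: trimesh.Trimesh) -> bool:
    return bool(mesh.is_watertight and mesh.is_winding_consistent)


def inflate(mesh: trimesh.Trimesh, iterations: int = 30,
            alpha: float = 0.5) -> trimesh.Trimesh:
    """Iterative inflation: each vertex moves to the convex combination of
    its old position (weight alpha) and the area-weighted mean of the
    centroids of its incident triangles. Connectivity is unchanged."""
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    v = mesh.vertices.copy()
    f = mesh.faces
    for _ in range(iterations):
        tri = v[f]
        cent = tri.mean(axis=1)
        area = 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
        acc = np.zeros_like(v)
        wsum = np.zeros(len(v))
        for j in range(3):
            np.add.at(acc, f[:, j], cent * area[:, None])
            np.add.at(wsum, f[:, j], area)
        ok = wsum > 1e-15
        target = v.copy()
        target[ok] = acc[ok] / wsum[ok, None]
        v = alpha * v + (1.0 - alpha) * target
    return trimesh.Trimesh(vertices=v, faces=f.copy(), process=False)


# ---------------------------------------------------------------------------
# patch partition (triangle dual graph)
# ---------------------------------------------------------------------------


def partition_patches(mesh: trimesh.Trimesh, k: int,
                      balance: float = 2.0, seed: int = 0) -> np.ndarray:
    """Partition the triangles into k edge-connected patches of similar
    area; returns a per-triangle patch index array.

    Recursive geometric bisection by area-weighted median planes along the
    locally longest principal axis gives compact, balanced pieces;
    a repair pass reattaches stray fragments and a bounded rebalancing pass
    moves boundary triangles until the max/min patch area ratio is at most
    ``balance`` (or no safe move remains).
    """
    n = len(mesh.faces)
    if not (1 <= k <= n):
        raise ValueError("k must lie in [1, number of triangles]")
    areas = mesh.area_faces.copy()
    cents = mesh.triangles_center
    labels = np.zeros(n, dtype=np.int64)
    _bisect(np.arange(n), k, 0, areas, cents, labels)
    adj = mesh.face_adjacency
    _repair_connectivity(labels, adj, areas, k)
    _rebalance(labels, adj, areas, k, balance)
    _repair_connectivity(labels, adj, areas, k)
    return labels


def _bisect(idx, k, base, areas, cents, labels):
    if k == 1:
        labels[idx] = base
        return
    k1 = k // 2
    frac = k1 / k
    c = cents[idx]
    w = areas[idx]
    mu = np.average(c, axis=0, weights=w)
    cov = (c - mu).T @ ((c - mu) * w[:, None])
    axis = np.linalg.eigh(cov)[1][:, -1]
    proj = c @ axis
    order = np.argsort(proj, kind="stable")
    cum = np.cumsum(w[order])
    split = int(np.searchsorted(cum, frac * cum[-1]))
    # each side must receive at least as many faces as patches it owes
    split = min(max(split, k1), len(idx) - (k - k1))
    left = idx[order[:split]]
    right = idx[order[split:]]
    _bisect(left, k1, base, areas, cents, labels)
    _bisect(right, k - k1, base + k1, areas, cents, labels)


def _patch_adjacency(labels, adj):
    from collections import defaultdict

    counts: dict = defaultdict(int)
    for a, b in adj:
        la, lb = labels[a], labels[b]
        if la != lb:
            counts[(la, lb)] += 1
            counts[(lb, la)] += 1
    return counts


def _repair_connectivity(labels, adj, areas, k):
    """Move every non-largest fragment of a patch to its best neighbor."""
    import networkx as nx

    for _ in range(8):
        moved = False
        G = nx.Graph()
        G.add_nodes_from(range(len(labels)))
        same = labels[adj[:, 0]] == labels[adj[:, 1]]
        G.add_edges_from(adj[same])
        for patch in range(k):
            faces = np.nonzero(labels == patch)[0]
            if len(faces) == 0:
                continue
            comps = sorted(nx.connected_components(G.subgraph(faces)),
                           key=lambda c: areas[list(c)].sum())
            for comp in comps[:-1]:
                comp = list(comp)
                # neighbor patch sharing the most boundary edges
                nb: dict = {}
                cset = set(comp)
                for a, b in adj:
                    if a in cset and labels[b] != patch:
                        nb[labels[b]] = nb.get(labels[b], 0) + 1
                    elif b in cset and labels[a] != patch:
                        nb[labels[a]] = nb.get(labels[a], 0) + 1
                if nb:
                    target = max(sorted(nb), key=lambda p: nb[p])
                    labels[comp] = target
                    moved = True
        if not moved:
            break


def _rebalance(labels, adj, areas, k, balance, max_passes: int = 60):
    """Greedy boundary moves from large to small patches, keeping donors
    connected."""
    import networkx as nx

    for _ in range(max_passes):
        patch_area = np.bincount(labels, weights=areas, minlength=k)
        nonempty = patch_area > 0
        if patch_area[nonempty].max() <= balance * \
                max(patch_area[nonempty].min(), 1e-300):
            break
        big = int(np.argmax(patch_area))
        # boundary faces of `big` adjacent to the smallest neighbor patch
        nb_faces: dict = {}
        for a, b in adj:
            if labels[a] == big and labels[b] != big:
                nb_faces.setdefault(labels[b], []).append(a)
            elif labels[b] == big and labels[a] != big:
                nb_faces.setdefault(labels[a], []).append(b)
        if not nb_faces:
            break
        target = min(nb_faces, key=lambda p: patch_area[p])
        moved = False
        faces_big = np.nonzero(labels == big)[0]
        G = nx.Graph()
        G.add_nodes_from(faces_big)
        same = (labels[adj[:, 0]] == big) & (labels[adj[:, 1]] == big)
        G.add_edges_from(adj[same])
        for f in sorted(set(nb_faces[target])):
            rest = [x for x in G.nodes if x != f]
            if rest and nx.is_connected(G.subgraph(rest)):
                labels[f] = target
                moved = True
                break
        if not moved:
            break


# ---------------------------------------------------------------------------
# dipoles
# ---------------------------------------------------------------------------


@dataclass
class Dipole:
    patch_id: int
    position: np.ndarray
    orientation: np.ndarray | None  # unit vector; None for triples
    area: float = 0.0
    triple: bool = False


def patch_dipoles(mesh: trimesh.Trimesh, labels: np.ndarray) -> list[Dipole]:
    """One equivalent oriented dipole per patch: position at the
    area-weighted patch centroid, orientation along the normalized
    area-weighted sum of triangle normals."""
    areas = mesh.area_faces
    cents = mesh.triangles_center
    normals = mesh.face_normals
    out = []
    for patch in np.unique(labels):
        sel = labels == patch
        a = areas[sel]
        total = float(a.sum())
        if total <= 0:
            raise ValueError(f"patch {patch} has zero area")
        pos = (cents[sel] * a[:, None]).sum(axis=0) / total
        nvec = (normals[sel] * a[:, None]).sum(axis=0)
        nn = np.linalg.norm(nvec)
        if nn < 1e-12:
            raise ValueError(f"patch {patch} has degenerate orientation")
        out.append(Dipole(int(patch), pos, nvec / nn, total))
    return out


def dipole_triples(gm_mask: np.ndarray, n: int, seed: int = 0,
                   spacing=(1.0, 1.0, 1.0)) -> list[Dipole]:
    """n unoriented dipole triples spread through gray matter by
    farthest-point sampling (quasi-uniform spacing)."""
    pts = np.argwhere(np.asarray(gm_mask, bool)) * np.asarray(spacing)
    if n < 1 or n > len(pts):
        raise ValueError("n must lie in [1, number of GM voxels]")
    rng = np.random.default_rng(seed)
    chosen = [int(rng.integers(len(pts)))]
    d = np.linalg.norm(pts - pts[chosen[0]], axis=1)
    for _ in range(n - 1):
        nxt = int(d.argmax())
        chosen.append(nxt)
        d = np.minimum(d, np.linalg.norm(pts - pts[nxt], axis=1))
    return [Dipole(i, pts[c], None, 0.0, True)
            for i, c in enumerate(chosen)]


# ---------------------------------------------------------------------------
# Talairach transform
# ---------------------------------------------------------------------------

# standard Talairach bounding-box extents (mm from the AC)
TAL_EXTENTS = {
    "right": 68.0, "left": 68.0,
    "anterior": 70.0, "posterior": 102.0,
    "superior": 74.0, "inferior": 42.0,
}


@dataclass
class TalairachFrame:
    """AC, PC and one mid-sagittal point defining the standard frame."""

    ac: np.ndarray
    pc: np.ndarray
    mid: np.ndarray

    def __post_init__(self) -> None:
        self.ac = np.asarray(self.ac, float)
        self.pc = np.asarray(self.pc, float)
        self.mid = np.asarray(self.mid, float)
        n = np.cross(self.pc - self.ac, self.mid - self.ac)
        if np.linalg.norm(n) < 1e-9:
            raise ValueError("AC, PC and mid-plane point are collinear")

    def rotation(self) -> np.ndarray:
        """Rows are the x (lateral), y (AC->anterior) and z axes."""
        y = self.ac - self.pc
        y = y / np.linalg.norm(y)
        n = np.cross(self.pc - self.ac, self.mid - self.ac)
        x = n / np.linalg.norm(n)
        z = np.cross(x, y)
        return np.stack([x, y, z])


def talairach_transform(frame: TalairachFrame, points: np.ndarray,
                        bounds: np.ndarray | None = None) -> np.ndarray:
    """Map points into Talairach space.

    Rigid part: AC at the origin, the AC-PC line along -y (PC posterior),
    the mid-sagittal plane at x = 0. Piecewise-linear part: each of the six
    half-axes is scaled so the data bounding box (computed from the points
    unless ``bounds`` gives [[xmin,xmax],[ymin,ymax],[zmin,zmax]] in the
    rigid frame) matches the standard Talairach extents. Topology of any
    mesh using these points is unchanged (the map is a homeomorphism).
    """
    pts = np.atleast_2d(np.asarray(points, float))
    R = frame.rotation()
    local = (pts - frame.ac) @ R.T
    if bounds is None:
        bounds = np.stack([local.min(axis=0), local.max(axis=0)], axis=1)
    else:
        bounds = np.asarray(bounds, float)
    pos_ext = np.array([TAL_EXTENTS["right"], TAL_EXTENTS["anterior"],
                        TAL_EXTENTS["superior"]])
    neg_ext = np.array([TAL_EXTENTS["left"], TAL_EXTENTS["posterior"],
                        TAL_EXTENTS["inferior"]])
    out = local.copy()
    for ax in range(3):
        hi = max(bounds[ax, 1], 1e-9)
        lo = min(bounds[ax, 0], -1e-9)
        pos = local[:, ax] > 0
        out[pos, ax] = local[pos, ax] * pos_ext[ax] / hi
        out[~pos, ax] = local[~pos, ax] * neg_ext[ax] / (-lo)
    return out
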