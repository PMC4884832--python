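"""Cell-complex morphometric analysis of voxel objects.

A 3-complex is built from a binary volume: one point per voxel, an edge for
every 26-connected pair, a triangle for every mutually connected triple, a
tetrahedron for every mutually connected quadruple. Free-pair (elementary)
collapses take the complex 3->2->1 while accumulating metrics:

* depth(f') = depth(f) + d(f, f') when a tetrahedron is removed by dropping
  its free face f (d = distance between cell centroids),
* wideness(e') = max(wideness(e'), wideness(e) + d(e, e')) and
  connectivity(e') = connectivity(e') + connectivity(e) + d(e, e') when a
  face is removed by dropping its free edge e.

The endpoint of the maximum-connectivity edge of the final 1-complex locates
the center of a highly connected object (the white-matter center); edges of
low wideness mark bottlenecks between the object's bulk and attached false
positives, which a wideness threshold cuts.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import ndimage as ndi


@dataclass
class CellComplex:
    """Simplicial cells over voxel points with collapse metrics."""

    points: np.ndarray                      # (n, 3) voxel coordinates
    edges: list[tuple[int, int]]
    faces: list[tuple[int, int, int]] = field(default_factory=list)
    tets: list[tuple[int, int, int, int]] = field(default_factory=list)
    depth: dict = field(default_factory=dict)        # face -> float
    wideness: dict = field(default_factory=dict)     # edge -> float
    connectivity: dict = field(default_factory=dict)  # edge -> float
    point_depth: np.ndarray | None = None  # boundary distance per point

    def centroid(self, cell) -> np.ndarray:
        return self.points[list(cell)].mean(axis=0)

    def d(self, a, b) -> float:
        return float(np.linalg.norm(self.centroid(a) - self.centroid(b)))

    def validate(self) -> None:
        """Every k-cell's (k-1)-faces must be present."""
        eset = set(self.edges)
        fset = set(self.faces)
        for f in self.faces:
            for e in combinations(f, 2):
                if e not in eset:
                    raise ValueError(f"face {f} missing edge {e}")
        for t in self.tets:
            for f in combinations(t, 3):
                if f not in fset:
                    raise ValueError(f"tet {t} missing face {f}")


def build_3complex(F: np.ndarray,
                   point_depth: np.ndarray | None = None) -> CellComplex:
    """Construct the 3-complex of a 26-connected voxel set.

    Triangles are 3-cliques and tetrahedra 4-cliques of the 26-adjacency
    graph (all lower faces then exist automatically). ``point_depth`` may
    supply a per-voxel depth field (e.g. the distance transform of the
    object the voxel set skeletonizes); it defaults to the distance
    transform of F itself. Edge metrics start at zero.
    """
    F = np.asarray(F, dtype=bool)
    pts = np.argwhere(F)
    if len(pts) == 0:
        raise ValueError("empty voxel set")
    index = -np.ones(F.shape, dtype=np.int64)
    index[tuple(pts.T)] = np.arange(len(pts))

    # neighbor lists via the 13 positive offsets (vectorized)
    nbrs: list[set[int]] = [set() for _ in range(len(pts))]
    edges: list[tuple[int, int]] = []
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
        if (dx, dy, dz) > (0, 0, 0)
    ]
    shape = F.shape
    for off in offsets:
        q = pts + off
        ok = np.all((q >= 0) & (q < shape), axis=1)
        j = np.full(len(pts), -1, dtype=np.int64)
        j[ok] = index[tuple(q[ok].T)]
        hit = j >= 0
        for a, b in zip(np.nonzero(hit)[0], j[hit]):
            a, b = int(a), int(b)
            lo, hi = (a, b) if a < b else (b, a)
            edges.append((lo, hi))
            nbrs[a].add(b)
            nbrs[b].add(a)
    edges.sort()

    faces: list[tuple[int, int, int]] = []
    tets: list[tuple[int, int, int, int]] = []
    for (i, j) in edges:
        common = nbrs[i] & nbrs[j]
        for k in sorted(c for c in common if c > j):
            faces.append((i, j, k))
            for m in sorted(c for c in (common & nbrs[k]) if c > k):
                tets.append((i, j, k, m))
    if point_depth is None:
        point_depth = ndi.distance_transform_edt(F)
    cc = CellComplex(pts, edges, faces, tets,
                     point_depth=np.asarray(point_depth)[tuple(pts.T)])
    for e in edges:
        cc.wideness[e] = 0.0
        cc.connectivity[e] = 0.0
    return cc


def collapse_3_to_2(cc: CellComplex) -> CellComplex:
    """Remove all tetrahedra, dropping one face each while the remaining
    three accumulate depth(f) + d(f, f').

    Preferred removals are elementary (tet, free-face) collapses, popped in
    order of increasing current depth then boundary distance then index. In
    a 26-adjacency clique complex faces commonly sit in several tetrahedra,
    so when no free pair exists the shallowest (most boundary-near)
    tetrahedron is removed with its shallowest face — an outside-in erosion
    that keeps the depth accumulation meaningful. No edges are touched, so
    the 1-skeleton is unchanged.
    """
    if not cc.tets:
        return cc
    face_tets: dict[tuple, set] = {f: set() for f in cc.faces}
    for t in cc.tets:
        for f in combinations(t, 3):
            face_tets[f].add(t)
    depth = {f: cc.depth.get(f, 0.0) for f in cc.faces}
    pd = cc.point_depth
    if pd is None:
        pd = np.zeros(len(cc.points))

    def prio(cell) -> float:
        return float(min(pd[i] for i in cell))

    live_tets = set(cc.tets)
    live_faces = set(cc.faces)
    free_heap = [(depth[f], prio(f), f) for f in cc.faces
                 if len(face_tets[f]) == 1]
    heapq.heapify(free_heap)
    forced_heap = [(prio(t), t) for t in cc.tets]
    heapq.heapify(forced_heap)
    while live_tets:
        pair = None
        while free_heap:
            _, _, f = heapq.heappop(free_heap)
            if f in live_faces and len(face_tets.get(f, ())) == 1:
                t = next(iter(face_tets[f]))
                if t in live_tets:
                    pair = (f, t)
                    break
        if pair is None:
            while forced_heap:
                _, t = heapq.heappop(forced_heap)
                if t in live_tets:
                    fs = [x for x in combinations(t, 3) if x in live_faces]
                    if fs:
                        f = min(fs, key=lambda x: (depth[x], prio(x), x))
                        pair = (f, t)
                    else:
                        live_tets.discard(t)
                    break
            if pair is None:
                if live_tets:  # all remaining tets lack live faces
                    live_tets.clear()
                break
        f, t = pair
        live_tets.discard(t)
        live_faces.discard(f)
        for f2 in combinations(t, 3):
            if f2 == f:
                continue
            s = face_tets.get(f2)
            if s is None:
                continue
            s.discard(t)
            if f2 in live_faces:
                nd = depth[f] + _dist(cc.points, f, f2)
                if nd > depth[f2]:
                    depth[f2] = nd
                if len(face_tets[f2]) == 1:
                    heapq.heappush(free_heap, (depth[f2], prio(f2), f2))
        face_tets.pop(f, None)
    return CellComplex(
        cc.points, list(cc.edges), sorted(live_faces), [],
        {f: depth[f] for f in live_faces},
        dict(cc.wideness), dict(cc.connectivity), cc.point_depth,
    )


def collapse_2_to_1(cc: CellComplex) -> CellComplex:
    """Remove all faces, accumulating wideness (max) and connectivity (sum)
    metrics on surviving edges.

    Preferred removals are elementary (face, free-edge) collapses in order
    of increasing face depth then boundary distance then index. When no free
    pair exists the shallowest face is discarded without removing an edge,
    so the 1-skeleton's connectivity is never broken (a free edge is never a
    bridge: the opposite two edges of its face provide a detour).
    """
    if cc.tets:
        raise ValueError("collapse tetrahedra first")
    if not cc.faces:
        return cc
    edge_faces: dict[tuple, set] = {e: set() for e in cc.edges}
    for f in cc.faces:
        for e in combinations(f, 2):
            edge_faces[e].add(f)
    wid = dict(cc.wideness)
    conn = dict(cc.connectivity)
    depth = dict(cc.depth)
    pd = cc.point_depth
    if pd is None:
        pd = np.zeros(len(cc.points))

    def prio(cell) -> float:
        return float(min(pd[i] for i in cell))

    live_faces = set(cc.faces)
    live_edges = set(cc.edges)

    def ekey(e):
        return (wid.get(e, 0.0), prio(e), e)

    # wavefront from the complex rim: free edges popped by ascending current
    # wideness, so wideness measures distance-to-rim (local structure width)
    free_heap = [ekey(e) for e in cc.edges if len(edge_faces[e]) == 1]
    heapq.heapify(free_heap)
    forced_heap = sorted((prio(f), f) for f in cc.faces)
    while live_faces:
        pair = None
        while free_heap:
            w0, _, e = heapq.heappop(free_heap)
            if e not in live_edges or len(edge_faces.get(e, ())) != 1:
                continue
            if w0 != wid.get(e, 0.0):  # stale priority; re-queue
                heapq.heappush(free_heap, ekey(e))
                continue
            f = next(iter(edge_faces[e]))
            if f in live_faces:
                pair = (e, f)
                break
        if pair is None:
            while forced_heap:
                f = heapq.heappop(forced_heap)[1]
                if f in live_faces:
                    live_faces.discard(f)  # discard face, keep all edges
                    for e2 in combinations(f, 2):
                        s = edge_faces.get(e2)
                        if s is not None:
                            s.discard(f)
                            if len(s) == 1 and e2 in live_edges:
                                heapq.heappush(free_heap, ekey(e2))
                    break
            continue
        e, f = pair
        live_faces.discard(f)
        live_edges.discard(e)
        for e2 in combinations(f, 2):
            if e2 == e:
                continue
            edge_faces[e2].discard(f)
            if e2 in live_edges:
                dd = _dist(cc.points, e, e2)
                w = wid.get(e, 0.0) + dd
                if w > wid.get(e2, 0.0):
                    wid[e2] = w
                conn[e2] = conn.get(e2, 0.0) + conn.get(e, 0.0) + dd
                if len(edge_faces[e2]) == 1:
                    heapq.heappush(free_heap, ekey(e2))
        edge_faces.pop(e, None)
    return CellComplex(
        cc.points, sorted(live_edges), [], [],
        {}, {e: wid.get(e, 0.0) for e in live_edges},
        {e: conn.get(e, 0.0) for e in live_edges}, cc.point_depth,
    )


def _dist(points: np.ndarray, a, b) -> float:
    ca = points[list(a)].mean(axis=0)
    cb = points[list(b)].mean(axis=0)
    return float(np.linalg.norm(ca - cb))


def find_center(cc: CellComplex) -> int:
    """Point index incident to the maximum-connectivity edge (ties broken
    lexicographically; the smaller endpoint index is returned)."""
    if not cc.edges:
        raise ValueError("edgeless complex has no center")
    best = max(cc.edges, key=lambda e: (cc.connectivity.get(e, 0.0),
                                        (-e[0], -e[1])))
    return best[0]


def wideness_cut(cc: CellComplex, w_threshold: float, center: int,
                 shape) -> np.ndarray:
    """Drop edges of wideness below threshold; keep the center's component.

    Returns the voxel mask of surviving points mapped back to the grid.
    """
    parent = list(range(len(cc.points)))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for e in cc.edges:
        if cc.wideness.get(e, 0.0) >= w_threshold:
            ra, rb = find(e[0]), find(e[1])
            if ra != rb:
                parent[ra] = rb
    root = find(center)
    keep = np.array([find(i) == root for i in range(len(cc.points))])
    mask = np.zeros(shape, dtype=bool)
    mask[tuple(cc.points[keep].T)] = True
    return mask


def dilate_restore(kept: np.ndarray, original: np.ndarray) -> np.ndarray:
    """Geodesic dilation of ``kept`` inside ``original`` to fixpoint."""
    kept = np.asarray(kept, bool)
    original = np.asarray(original, bool)
    if np.any(kept & ~original):
        raise ValueError("kept must be a subset of original")
    return ndi.binary_propagation(
        kept, structure=np.ones((3, 3, 3), bool), mask=original
    )


def partition_by_cores(cc: CellComplex, w_threshold: float, center: int,
                       shape, merge_ratio: float = 0.6
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Split skeleton points into the center's structure and the rest.

    Edges with wideness >= threshold define *cores* (thick structure).
    A false positive presents a NARROW bottleneck, so a core is separated
    from the center's structure only when the widest path connecting them
    pinches below ``merge_ratio`` times the smaller of the two cores' peak
    wideness; otherwise the apparent split is just texture in one structure
    and the cores are merged. Peripheral points (attached only through thin
    edges) are assigned to the graph-nearest core, so a lobe keeps its thin
    fringe while a genuine bottleneck path is split mid-way (ties go to the
    far side). Returns (kept_mask, removed_mask) over the voxel grid.
    """
    from collections import deque

    n = len(cc.points)
    adj: list[list[int]] = [[] for _ in range(n)]
    for a, b in cc.edges:
        adj[a].append(b)
        adj[b].append(a)
    # cores: components of the high-wideness subgraph
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    in_core = np.zeros(n, dtype=bool)
    for e in cc.edges:
        if cc.wideness.get(e, 0.0) >= w_threshold:
            in_core[e[0]] = in_core[e[1]] = True
            ra, rb = find(e[0]), find(e[1])
            if ra != rb:
                parent[ra] = rb
    if not in_core.any():
        in_core[center] = True
    center_root = find(center) if in_core[center] else -1

    if center_root >= 0:
        # peak wideness per core
        peak: dict[int, float] = {}
        for e in cc.edges:
            w = cc.wideness.get(e, 0.0)
            if w >= w_threshold:
                r = find(e[0])
                peak[r] = max(peak.get(r, 0.0), w)
        # single-linkage over descending wideness: when the groups of two
        # cores first join, the current edge wideness is the bottleneck of
        # the widest path between them
        parent2 = list(range(n))

        def find2(a):
            while parent2[a] != a:
                parent2[a] = parent2[parent2[a]]
                a = parent2[a]
            return a

        group_cores: dict[int, set] = {}
        for i in range(n):
            if in_core[i]:
                group_cores.setdefault(find2(i), set()).add(find(i))
        merged_with_center = {center_root}
        for e in sorted(cc.edges, key=lambda e: -cc.wideness.get(e, 0.0)):
            w = cc.wideness.get(e, 0.0)
            ra, rb = find2(e[0]), find2(e[1])
            if ra == rb:
                continue
            ca = group_cores.pop(ra, set())
            cb = group_cores.pop(rb, set())
            parent2[ra] = rb
            joined = ca | cb
            if joined:
                group_cores[find2(rb)] = joined
            if center_root in joined and len(joined) > 1:
                for core in joined:
                    if core in merged_with_center or core == center_root:
                        continue
                    limit = merge_ratio * min(peak.get(core, 0.0),
                                              peak.get(center_root, 0.0))
                    if w >= limit:
                        merged_with_center.add(core)
        keep_cores = merged_with_center
    else:
        keep_cores = set()

    # multi-source BFS over the full graph: nearest core claims the point
    label = np.full(n, -1, dtype=np.int64)
    dq = deque()
    for i in range(n):
        if in_core[i]:
            label[i] = find(i)
            dq.append(i)
    while dq:
        i = dq.popleft()
        for j in adj[i]:
            if label[j] < 0:
                label[j] = label[i]
                dq.append(j)
    if center_root < 0:
        # center fell outside all cores: keep its plain component
        comp = np.zeros(n, bool)
        dq = deque([center])
        comp[center] = True
        while dq:
            i = dq.popleft()
            for j in adj[i]:
                if not comp[j]:
                    comp[j] = True
                    dq.append(j)
        keep = comp
    else:
        keep = np.isin(label, sorted(keep_cores))
    kept_mask = np.zeros(shape, bool)
    removed_mask = np.zeros(shape, bool)
    kept_mask[tuple(cc.points[keep].T)] = True
    removed_mask[tuple(cc.points[~keep].T)] = True
    return kept_mask, removed_mask


def influence_restore(kept: np.ndarray, removed: np.ndarray,
                      original: np.ndarray) -> np.ndarray:
    """Competitive geodesic restoration after a bottleneck cut.

    Voxels of ``original`` are assigned to the skeleton seed set (kept or
    removed) whose geodesic influence zone reaches them first; ties go to
    ``removed`` so the cut surface stays with the discarded side. Unlike a
    plain geodesic dilation of ``kept``, the discarded skeleton acts as a
    competing front, so restoration cannot leak back through the volume of
    a cut bottleneck.
    """
    original = np.asarray(original, bool)
    a = np.asarray(kept, bool) & original
    b = np.asarray(removed, bool) & original
    s = np.ones((3, 3, 3), bool)
    while True:
        grown_a = ndi.binary_dilation(a, s) & original & ~a & ~b
        grown_b = ndi.binary_dilation(b, s) & original & ~a & ~b
        both = grown_a & grown_b
        grown_a &= ~both
        na = grown_a.any()
        nb = (grown_b.any() or both.any())
        if not na and not nb:
            return a
        a |= grown_a
        b |= grown_b | both


def otsu_wideness_threshold(cc: CellComplex) -> float:
    """Automatic bottleneck threshold: Otsu split of edge wideness values."""
    from skimage.filters import threshold_otsu

    w = np.array([cc.wideness.get(e, 0.0) for e in cc.edges])
    if len(w) == 0 or w.max() == w.min():
        return 0.0
    return float(threshold_otsu(w))


def analyze(F: np.ndarray, point_depth: np.ndarray | None = None,
            seed_from_depth: bool = True):
    """Full chain: build, collapse 3->2->1. Returns the final 1-complex.

    When ``seed_from_depth`` is set, edge wideness and connectivity start at
    the smaller endpoint depth (the local half-thickness of the structure
    the skeleton represents) instead of zero, and the collapse recurrences
    accumulate on top. Curve-like regions of a skeleton carry few or no
    faces, so without this seed their edges would keep zero metrics and
    bottlenecks could not be ranked against the object's bulk.
    """
    cc = build_3complex(F, point_depth)
    if seed_from_depth and cc.point_depth is not None:
        for e in cc.edges:
            w = float(min(cc.point_depth[e[0]], cc.point_depth[e[1]]))
            cc.wideness[e] = w
            cc.connectivity[e] = w
    cc = collapse_3_to_2(cc)
    cc = collapse_2_to_1(cc)
    return cc
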