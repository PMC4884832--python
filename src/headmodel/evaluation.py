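"""Segmentation evaluation: Dice overlap, soft-probability counting, and
the geodesic partition of brain false positives into cerebrum/cerebellum."""

from __future__ import annotations

from collections import deque

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .phantom import LabelVolume, Tissue

_OFF26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def confusion(seg, truth) -> tuple[float, float, float]:
    """(TP, FP, FN) for boolean masks or probability fields in [0, 1].

    Counts are probability sums (soft counting): for truth t and
    segmentation probability p, TP = sum(p*t), FP = sum(p*(1-t)),
    FN = sum((1-p)*t). With 0/1 inputs this reduces to discrete counting.
    """
    p = np.asarray(seg, dtype=float)
    t = np.asarray(truth, dtype=float)
    if p.shape != t.shape:
        raise ValueError("segmentation and truth shapes differ")
    tp = float((p * t).sum())
    fp = float((p * (1.0 - t)).sum())
    fn = float(((1.0 - p) * t).sum())
    return tp, fp, fn


def dice(seg, truth, tissue: int | None = None) -> float:
    """Dice overlap 2TP / (2TP + FP + FN).

    ``seg``/``truth`` are boolean masks, probability fields, or label
    volumes combined with ``tissue``. A tissue absent from both is scored
    1.0; absent from the truth only scores 0.0.
    """
    if tissue is not None:
        seg = (seg.data if isinstance(seg, LabelVolume) else
               np.asarray(seg)) == tissue
        truth = (truth.data if isinstance(truth, LabelVolume) else
                 np.asarray(truth)) == tissue
    tp, fp, fn = confusion(seg, truth)
    denom = 2 * tp + fp + fn
    if denom == 0:
        return 1.0
    return 2 * tp / denom


def partition_false_positives(fp_brain: np.ndarray,
                              tp_cerebrum: np.ndarray,
                              tp_cerebellum: np.ndarray):
    """Split brain false positives between cerebrum and cerebellum.

    Each FP voxel goes to cerebrum iff its geodesic path inside FP-Brain to
    the cerebrum true positives is strictly shorter than any path to the
    cerebellum true positives; ties and unreachable voxels go to the
    cerebellum. Distances are BFS steps over 26-adjacency, entering the FP
    set from voxels adjacent to each TP set.
    """
    fp = np.asarray(fp_brain, bool)
    tpc = np.asarray(tp_cerebrum, bool)
    tpb = np.asarray(tp_cerebellum, bool)
    if (fp & tpc).any() or (fp & tpb).any() or (tpc & tpb).any():
        raise ValueError("FP and TP sets must be disjoint")
    d_cer = _bfs_distance(fp, tpc)
    d_ceb = _bfs_distance(fp, tpb)
    to_cerebrum = fp & (d_cer < d_ceb)
    to_cerebellum = fp & ~to_cerebrum
    return to_cerebrum, to_cerebellum


def _bfs_distance(region: np.ndarray, sources: np.ndarray) -> np.ndarray:
    """BFS step counts within ``region`` from voxels 26-adjacent to
    ``sources`` (those start at distance 1); unreachable: +inf."""
    dist = np.full(region.shape, np.inf)
    seeds = region & ndi.binary_dilation(sources,
                                         structure=np.ones((3, 3, 3), bool))
    dq = deque()
    for v in map(tuple, np.argwhere(seeds)):
        dist[v] = 1.0
        dq.append(v)
    shape = region.shape
    while dq:
        x, y, z = dq.popleft()
        d = dist[x, y, z] + 1.0
        for dx, dy, dz in _OFF26:
            u = (x + dx, y + dy, z + dz)
            if 0 <= u[0] < shape[0] and 0 <= u[1] < shape[1] \
                    and 0 <= u[2] < shape[2] and region[u] \
                    and dist[u] > d:
                dist[u] = d
                dq.append(u)
    return dist


def report(cases: list[tuple], tissues=None) -> pd.DataFrame:
    """Per-tissue Dice table over (model, truth) LabelVolume pairs, with
    mean and sample standard deviation (ddof=1) rows across cases."""
    if not cases:
        raise ValueError("no cases to evaluate")
    if tissues is None:
        tissues = {"wm": Tissue.WM_ALL, "gm": Tissue.GM_ALL,
                   "csf": (Tissue.CSF,)}
    rows = []
    for i, (model, truth) in enumerate(cases):
        md = model.data if isinstance(model, LabelVolume) else model
        td = truth.data if isinstance(truth, LabelVolume) else truth
        row = {"case": i}
        for name, codes in tissues.items():
            row[name] = dice(np.isin(md, codes), np.isin(td, codes))
        rows.append(row)
    df = pd.DataFrame(rows).set_index("case")
    summary = pd.DataFrame(
        {c: [df[c].mean(), df[c].std(ddof=1) if len(df) > 1 else 0.0]
         for c in df.columns}, index=["mean", "sd"])
    return pd.concat([df, summary])
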