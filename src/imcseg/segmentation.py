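"""Weighted density clustering of pixels and local-maxima cluster splitting.

Positive-weight pixels are clustered with DBSCAN under the Manhattan metric,
using the transformed pixel intensity as a *sample weight*: a pixel is a core
point iff the weights of all pixels within ``eps`` (itself included) sum to at
least ``min_weight``. Clusters of touching cells are then split at the local
maxima of the background-corrected channel, each pixel joining its nearest
contained maximum.

Determinism contract (DBSCAN leaves these implementation-defined, so they are
fixed here):

* a border point joins the cluster of its nearest core point (Manhattan
  distance); equidistant cores in different clusters → the lowest cluster id;
* cluster ids are ordered by the row-major position of each cluster's first
  core pixel while border points are assigned, and the final labels are
  re-compacted by the row-major position of each cluster's first member pixel;
* the result is independent of input point order.
"""

from __future__ import annotations

import math
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .core import ChannelImage, LabelMap, Region, WeightMap

__all__ = [
    "WeightedPoint",
    "points_from_weight_map",
    "weighted_dbscan",
    "segment_weight_map",
    "detect_local_maxima",
    "split_clusters",
    "regions_from_labels",
]


class WeightedPoint(NamedTuple):
    """A positive-weight pixel fed to the density clustering."""

    row: int
    col: int
    weight: float


def points_from_weight_map(weights: WeightMap) -> list[WeightedPoint]:
    """Extract the positive-weight pixels of a weight map as clustering input."""
    rr, cc = np.nonzero(weights.data > 0)
    w = weights.data[rr, cc]
    return [WeightedPoint(int(r), int(c), float(v)) for r, c, v in zip(rr, cc, w)]


def _shifted(a: np.ndarray, dr: int, dc: int, fill=0) -> np.ndarray:
    """out[i, j] = a[i + dr, j + dc], out-of-bounds positions filled."""
    H, W = a.shape
    out = np.full_like(a, fill)
    rs = slice(max(0, dr), H + min(0, dr))
    cs = slice(max(0, dc), W + min(0, dc))
    rd = slice(max(0, -dr), H + min(0, -dr))
    cd = slice(max(0, -dc), W + min(0, -dc))
    out[rd, cd] = a[rs, cs]
    return out


def _manhattan_offsets(eps: float) -> list[tuple[int, int]]:
    r = int(math.floor(eps))
    return [
        (dr, dc)
        for dr in range(-r, r + 1)
        for dc in range(-r, r + 1)
        if abs(dr) + abs(dc) <= eps
    ]


def _dbscan_grid(w: np.ndarray, eps: float, min_weight: float) -> np.ndarray:
    """Weighted DBSCAN on a dense weight grid; returns int labels (0 = noise)."""
    H, W = w.shape
    offsets = _manhattan_offsets(eps)

    # core condition: eps-neighbourhood weight sum (self included) >= min_weight
    nbr_sum = np.zeros_like(w)
    for dr, dc in offsets:
        nbr_sum += _shifted(w, dr, dc)
    core = (w > 0) & (nbr_sum >= min_weight)

    labels = np.zeros((H, W), dtype=np.int32)
    if not core.any():
        return labels

    # connected components of core pixels under "Manhattan distance <= eps"
    core_flat = np.flatnonzero(core.ravel())
    n_core = core_flat.size
    node_of = np.full(H * W, -1, dtype=np.int64)
    node_of[core_flat] = np.arange(n_core)
    ci = core_flat // W
    cj = core_flat % W
    half = [(dr, dc) for dr, dc in offsets if (dr, dc) > (0, 0)]
    rows, cols = [], []
    for dr, dc in half:
        qi = ci + dr
        qj = cj + dc
        ok = (qi >= 0) & (qi < H) & (qj >= 0) & (qj < W)
        qn = node_of[qi[ok] * W + qj[ok]]
        hit = qn >= 0
        rows.append(np.arange(n_core)[ok][hit])
        cols.append(qn[hit])
    graph = coo_matrix(
        (np.ones(sum(len(r) for r in rows)), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_core, n_core),
    )
    _, comp = connected_components(graph, directed=False)

    # order clusters by the row-major position of their first core pixel
    first_core = np.full(comp.max() + 1, np.iinfo(np.int64).max, dtype=np.int64)
    np.minimum.at(first_core, comp, core_flat)
    rank = np.empty_like(first_core)
    rank[np.argsort(first_core)] = np.arange(1, first_core.size + 1)
    labels.ravel()[core_flat] = rank[comp]

    # border points: positive weight, non-core, within eps of a core point;
    # nearest core wins, equidistant ties go to the lowest cluster id
    border = (w > 0) & ~core
    if border.any():
        big = np.iinfo(np.int32).max
        best_d = np.full((H, W), np.inf)
        best_id = np.full((H, W), big, dtype=np.int64)
        for dr, dc in offsets:
            if dr == 0 and dc == 0:
                continue
            d = abs(dr) + abs(dc)
            lab = _shifted(labels, dr, dc)
            cand = border & (lab > 0)
            upd = cand & ((d < best_d) | ((d == best_d) & (lab < best_id)))
            best_d[upd] = d
            best_id[upd] = lab[upd]
        hit = border & (best_id < big)
        labels[hit] = best_id[hit]

    return _compact_labels(labels)


def _compact_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel to 1..K ordered by each cluster's first member pixel (row-major)."""
    flat = labels.ravel()
    pos = np.flatnonzero(flat)
    if pos.size == 0:
        return labels
    old = flat[pos]
    k = old.max()
    first = np.full(k + 1, np.iinfo(np.int64).max, dtype=np.int64)
    np.minimum.at(first, old, pos)
    present = np.flatnonzero(first < np.iinfo(np.int64).max)
    remap = np.zeros(k + 1, dtype=labels.dtype)
    remap[present[np.argsort(first[present])]] = np.arange(1, present.size + 1)
    out = remap[labels]
    return out


def weighted_dbscan(
    points: Iterable[WeightedPoint | tuple[int, int, float]],
    shape: tuple[int, int],
    eps: float,
    min_weight: float,
) -> LabelMap:
    """Cluster weighted pixels; returns a label map (0 = noise).

    ``points`` may be given in any order; duplicate coordinates are rejected.
    """
    if eps <= 0 or min_weight <= 0:
        raise ValueError("eps and min_weight must be positive")
    H, W = shape
    w = np.zeros((H, W))
    seen = np.zeros((H, W), dtype=bool)
    for r, c, wt in points:
        if not (0 <= r < H and 0 <= c < W):
            raise ValueError(f"point ({r}, {c}) outside image of shape {shape}")
        if wt <= 0:
            raise ValueError("point weights must be positive")
        if seen[r, c]:
            raise ValueError(f"duplicate point at ({r}, {c})")
        seen[r, c] = True
        w[r, c] = wt
    return LabelMap(_dbscan_grid(w, eps, min_weight))


def segment_weight_map(weights: WeightMap, eps: float, min_weight: float) -> LabelMap:
    """Convenience wrapper clustering the positive pixels of a weight map."""
    if eps <= 0 or min_weight <= 0:
        raise ValueError("eps and min_weight must be positive")
    return LabelMap(_dbscan_grid(weights.data, eps, min_weight))


def detect_local_maxima(
    img_bc: ChannelImage, footprint_radius: int = 1
) -> set[tuple[int, int]]:
    """Detect strictly positive local maxima of a background-corrected channel.

    A pixel is a candidate if its value is positive and not below any
    neighbour within a (2r+1)×(2r+1) footprint. Connected plateaus of
    equal-valued candidates (within the same footprint distance) are merged
    and represented by their lexicographically smallest ``(row, col)``.
    """
    if footprint_radius < 1:
        raise ValueError("footprint_radius must be >= 1")
    a = img_bc.data
    size = 2 * footprint_radius + 1
    mx = ndimage.maximum_filter(a, size=size, mode="constant", cval=-np.inf)
    cand = (a > 0) & (a >= mx)
    coords = np.argwhere(cand)  # row-major, hence lexicographically sorted
    if coords.size == 0:
        return set()
    values = a[coords[:, 0], coords[:, 1]]

    # merge equal-valued plateaus: union-find over candidate pairs within the
    # footprint (Chebyshev distance <= r) that share the same value
    parent = np.arange(len(coords))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    tree = cKDTree(coords)
    for i, j in tree.query_pairs(footprint_radius, p=np.inf):
        if values[i] == values[j]:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[max(ri, rj)] = min(ri, rj)

    reps = {find(i) for i in range(len(coords))}
    return {(int(coords[i, 0]), int(coords[i, 1])) for i in reps}


def split_clusters(
    labels: LabelMap, maxima: Iterable[tuple[int, int]]
) -> LabelMap:
    """Split clusters containing several local maxima into one cluster per maximum.

    Pixels of a split cluster join their nearest contained maximum (Euclidean
    distance; ties go to the lexicographically smaller maximum coordinate).
    Clusters with zero or one contained maximum are left unchanged. Output ids
    are re-compacted to 1..K ordered by each cluster's first member pixel.
    """
    arr = labels.data
    H, W = arr.shape
    maxima = sorted(set((int(r), int(c)) for r, c in maxima))
    for r, c in maxima:
        if not (0 <= r < H and 0 <= c < W):
            raise ValueError(f"maximum ({r}, {c}) outside image of shape {arr.shape}")

    by_cluster: dict[int, list[tuple[int, int]]] = {}
    for r, c in maxima:
        lab = int(arr[r, c])
        if lab > 0:
            by_cluster.setdefault(lab, []).append((r, c))

    out = arr.astype(np.int32, copy=True)
    next_id = int(arr.max()) + 1
    for lab, maxs in by_cluster.items():
        if len(maxs) < 2:
            continue
        pix = np.argwhere(arr == lab)
        m = np.asarray(maxs, dtype=float)  # already lexicographically sorted
        d2 = ((pix[:, None, :] - m[None, :, :]) ** 2).sum(axis=2)
        assign = np.argmin(d2, axis=1)  # first minimum = lex-smaller maximum
        for k in range(len(maxs)):
            sel = pix[assign == k]
            out[sel[:, 0], sel[:, 1]] = next_id
            next_id += 1
    return LabelMap(_compact_labels(out))


def regions_from_labels(labels: LabelMap, marker: str) -> list[Region]:
    """Materialise each labeled cluster as a :class:`Region` for the marker."""
    arr = labels.data
    rr, cc = np.nonzero(arr)
    regions: dict[int, set[tuple[int, int]]] = {}
    for r, c, lab in zip(rr, cc, arr[rr, cc]):
        regions.setdefault(int(lab), set()).add((int(r), int(c)))
    return [
        Region(region_id=lab, marker=marker, pixels=frozenset(pix))
        for lab, pix in sorted(regions.items())
    ]
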