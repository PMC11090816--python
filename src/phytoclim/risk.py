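"""Euclidean-distance risk indices on phytoclimate surfaces.

Three per-cell indices compare the ambient and future 14-dimensional
growth-form suitability surfaces:

* local change — distance between a cell's ambient and future vectors;
* novelty — minimum distance of a cell's *future* vector to the global
  pool of *ambient* vectors (how unlike anything that exists today);
* disappearance — minimum distance of a cell's *ambient* vector to the
  global pool of *future* vectors (how unlike anything that will exist).

Pools span all land cells globally, including the focal cell's own
counterpart, so novelty and disappearance are bounded above by local
change. Future cells are assigned the zone of their nearest ambient
analogue unless their novelty exceeds the significance threshold, in
which case they are designated novel. Nearest-analogue search uses a
k-d tree with an exact lowest-index tie-break.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .exceptions import EmptyPoolError

__all__ = [
    "NOVEL",
    "phyto_distance",
    "local_change",
    "novelty",
    "disappearance",
    "nearest_analogue",
    "assign_future_zones",
    "ensemble_median",
    "area_fraction_significant",
]

#: label used for future cells without a close ambient analogue
NOVEL = -1


def phyto_distance(a, b) -> float:
    """Euclidean distance between two growth-form suitability vectors."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError(f"vector shapes differ: {a.shape} vs {b.shape}")
    return float(np.sqrt(((a - b) ** 2).sum()))


def _check_surfaces(a, b):
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError(f"surface shapes differ: {a.shape} vs {b.shape}")
    if a.ndim != 2:
        raise ValueError("surfaces must be (n_cells, n_forms) arrays")
    return a, b


def local_change(ambient: np.ndarray, future: np.ndarray) -> np.ndarray:
    """Per-cell distance between ambient and future phytoclimates."""
    ambient, future = _check_surfaces(ambient, future)
    return np.sqrt(((future - ambient) ** 2).sum(axis=1))


def nearest_analogue(pool: np.ndarray, queries: np.ndarray):
    """(distance, index into pool) of each query's nearest pool vector.

    Exact: backed by a k-d tree, with ties resolved to the lowest pool
    index by a secondary ball search at the found radius.
    """
    pool = np.asarray(pool, float)
    queries = np.asarray(queries, float)
    if pool.size == 0:
        raise EmptyPoolError("empty analogue pool")
    tree = cKDTree(pool)
    dist, idx = tree.query(queries, k=1)
    # lowest-index tie-break: look for equal-distance pool members
    for i in np.flatnonzero(dist >= 0):
        ties = tree.query_ball_point(queries[i], r=dist[i] * (1 + 1e-12) + 1e-300)
        if len(ties) > 1:
            exact = [j for j in ties
                     if np.sqrt(((pool[j] - queries[i]) ** 2).sum()) <= dist[i]]
            if exact:
                idx[i] = min(exact)
    # recompute distances elementwise so the accelerated path returns the
    # same floating-point values as a direct O(N^2) scan
    dist = np.sqrt(((queries - pool[idx]) ** 2).sum(axis=-1))
    return dist, idx


def novelty(future: np.ndarray, ambient_pool: np.ndarray) -> np.ndarray:
    """Min distance of each future cell to the global ambient pool."""
    future = np.asarray(future, float)
    dist, _ = nearest_analogue(ambient_pool, future)
    return dist


def disappearance(ambient: np.ndarray, future_pool: np.ndarray) -> np.ndarray:
    """Min distance of each ambient cell to the global future pool."""
    ambient = np.asarray(ambient, float)
    dist, _ = nearest_analogue(future_pool, ambient)
    return dist


def assign_future_zones(
    future: np.ndarray,
    ambient: np.ndarray,
    ambient_labels: np.ndarray,
    threshold: float,
) -> np.ndarray:
    """Zone of each future cell: that of its nearest ambient analogue,
    or :data:`NOVEL` where novelty exceeds the threshold."""
    ambient_labels = np.asarray(ambient_labels)
    if ambient_labels.shape[0] != np.asarray(ambient).shape[0]:
        raise ValueError("ambient labels must cover the ambient pool")
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    dist, idx = nearest_analogue(ambient, future)
    labels = ambient_labels[idx].copy()
    labels[dist > threshold] = NOVEL
    return labels


def ensemble_median(members: list[np.ndarray] | np.ndarray) -> np.ndarray:
    """Cellwise (and per-form, when 2-D members) median across an ensemble."""
    members = [np.asarray(m, float) for m in members]
    if not members:
        raise ValueError("need at least one ensemble member")
    shape = members[0].shape
    if any(m.shape != shape for m in members):
        raise ValueError("ensemble members are on different grids")
    return np.median(np.stack(members), axis=0)


def area_fraction_significant(index: np.ndarray, threshold: float) -> float:
    """Fraction of (land) cells whose index strictly exceeds the threshold.

    On an equal-area grid the cell-count fraction equals the area
    fraction. ``index`` must already be restricted to land cells.
    """
    index = np.asarray(index, float)
    if index.size == 0:
        raise EmptyPoolError("no land cells in index surface")
    return float((index > threshold).mean())
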