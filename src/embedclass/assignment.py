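"""Discretizing query tiles on the 2-D map.

Each query tile is assigned by examining its k nearest *reference* points
(2-D Euclidean; query tiles never vote): if the modal class holds at least
the purity fraction of those k neighbors the tile is discretized to that
class, otherwise it is an outlier/anomalous point. An optional distance
guard additionally calls a tile OUTLIER when it lies in unoccupied space —
its k-th reference neighbor farther than an a-priori radius derived from the
reference map itself.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
from scipy.spatial import cKDTree

from ._types import OUTLIER, TileAssignment

__all__ = [
    "assign_tile",
    "assign_tiles",
    "tabulate",
    "unoccupied_radius",
]


def _k_nearest(query_xy: np.ndarray, ref_xy: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k nearest reference points; distance ties broken by index."""
    d = np.linalg.norm(ref_xy - query_xy, axis=1)
    order = np.argsort(d, kind="stable")  # stable sort => ties by reference order
    return order[:k]


def assign_tile(
    query_xy: np.ndarray,
    ref_xy: np.ndarray,
    ref_labels: np.ndarray,
    tile_id: str = "?",
    knn_k: int = 25,
    knn_purity: float = 0.85,
    max_neighbor_distance: float | None = None,
) -> TileAssignment:
    """Assign one query point to a trained class or OUTLIER.

    The k nearest reference points (2-D Euclidean, distance ties broken by
    reference order) are examined; the call is the modal class when its
    fraction reaches ``knn_purity``, else OUTLIER. If
    ``max_neighbor_distance`` is given and the k-th neighbor is farther than
    it, the tile is in unoccupied space and is OUTLIER regardless of purity.
    """
    ref_xy = np.asarray(ref_xy, dtype=float)
    ref_labels = np.asarray(ref_labels)
    if ref_xy.shape[0] < knn_k:
        raise ValueError(f"reference has {ref_xy.shape[0]} points, need >= knn_k={knn_k}")
    query_xy = np.asarray(query_xy, dtype=float)
    idx = _k_nearest(query_xy, ref_xy, knn_k)
    counts = Counter(ref_labels[idx].tolist())
    # modal class: ties by label order for determinism
    modal, modal_n = min(counts.items(), key=lambda kv: (-kv[1], str(kv[0])))
    purity = modal_n / knn_k
    call = str(modal) if purity >= knn_purity else OUTLIER
    if max_neighbor_distance is not None:
        kth = float(np.linalg.norm(ref_xy[idx[-1]] - query_xy))
        if kth > max_neighbor_distance:
            call = OUTLIER
    return TileAssignment(
        tile_id=tile_id,
        call=call,
        neighbor_class_counts={str(k): int(v) for k, v in sorted(counts.items())},
        purity=purity,
    )


def unoccupied_radius(
    ref_xy: np.ndarray, knn_k: int = 25, factor: float = 3.0
) -> float:
    """A-priori radius separating occupied from unoccupied map space.

    Computed from the reference map alone, before any query is seen: the
    95th percentile over reference points of the distance to their own k-th
    nearest reference neighbor, scaled by ``factor``. Query tiles whose k-th
    reference neighbor lies beyond this radius sit in empty space between
    the clusters.
    """
    ref_xy = np.asarray(ref_xy, dtype=float)
    tree = cKDTree(ref_xy)
    d, _ = tree.query(ref_xy, k=knn_k + 1)  # +1: self at distance 0
    return factor * float(np.quantile(d[:, -1], 0.95))


def assign_tiles(
    query_xy: np.ndarray,
    ref_xy: np.ndarray,
    ref_labels: np.ndarray,
    tile_ids: list[str] | None = None,
    knn_k: int = 25,
    knn_purity: float = 0.85,
    max_neighbor_distance: float | None = None,
) -> list[TileAssignment]:
    """Assign every query point; see :func:`assign_tile`."""
    query_xy = np.atleast_2d(np.asarray(query_xy, dtype=float))
    if tile_ids is None:
        tile_ids = [f"q_{i:04d}" for i in range(query_xy.shape[0])]
    return [
        assign_tile(
            query_xy[i], ref_xy, ref_labels, tile_id=tile_ids[i],
            knn_k=knn_k, knn_purity=knn_purity,
            max_neighbor_distance=max_neighbor_distance,
        )
        for i in range(query_xy.shape[0])
    ]


def tabulate(assignments: list[TileAssignment]) -> dict[str, int]:
    """Contingency table of calls (classes with zero tiles omitted)."""
    if not assignments:
        raise ValueError("cannot tabulate an empty assignment list")
    counts = Counter(a.call for a in assignments)
    return {k: int(counts[k]) for k in sorted(counts)}
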