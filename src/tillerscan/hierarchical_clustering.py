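"""Hierarchical clustering (HC): count tillers inside one wheat cluster.

Adjacent tillers that the layering step cannot separate are resolved by
agglomerative clustering of the cluster's stem-zone points under Euclidean
distance.  Classes are merged while the smallest inter-class distance does
not exceed a stop threshold ``d_stop`` (default 2 cm, the minimum distance
between two field-grown wheat tillers); the surviving class count is the
tiller number of that cluster.

Under single linkage the result at threshold d equals the number of
connected components of the graph joining points closer than d — the
identity the test-suite oracle exploits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .adaptive_layering import ClusterSegment

__all__ = [
    "HCConfig",
    "SimilarityMatrix",
    "Dendrogram",
    "TillerCountPerCluster",
    "euclidean_distance",
    "build_similarity",
    "agglomerate",
    "count_tillers_in_cluster",
]

_LINKAGES = ("single", "complete", "average")


@dataclass
class HCConfig:
    """Parameters of the tiller-counting step.

    d_stop
        Distance threshold ending agglomeration, meters.  Default 0.02 m —
        the assumed minimum spacing between distinct tillers in the field.
    linkage
        Inter-class distance rule: ``single`` (nearest members, default),
        ``complete`` or ``average``.
    use_points
        ``stem_only`` feeds only stem-zone points to the clustering
        (leaves would be miscounted as tillers); ``all`` uses every
        segment point.
    """

    d_stop: float = 0.02
    linkage: str = "single"
    use_points: str = "stem_only"

    def __post_init__(self) -> None:
        if self.d_stop <= 0:
            raise ValueError("d_stop must be positive")
        if self.linkage not in _LINKAGES:
            raise ValueError(f"linkage must be one of {_LINKAGES}")
        if self.use_points not in ("stem_only", "all"):
            raise ValueError("use_points must be 'stem_only' or 'all'")


@dataclass
class SimilarityMatrix:
    """Dense N x N matrix of pairwise Euclidean distances (meters)."""

    d: np.ndarray

    @property
    def size(self) -> int:
        return self.d.shape[0]


@dataclass
class Dendrogram:
    """Merge history: ordered (class_a, class_b, merge_distance) triples."""

    merges: list[tuple[int, int, float]]
    leaf_count: int


@dataclass
class TillerCountPerCluster:
    """Tiller count and per-point class assignment for one wheat cluster."""

    cluster_id: int
    tiller_count: int
    labels: np.ndarray  # class id 0..k-1 per clustered point
    dendrogram: Dendrogram
    point_index: np.ndarray | None = None  # indices into the parent RowCloud


def euclidean_distance(a, b) -> float:
    """Plain L2 distance between two 3D points, in meters."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.sqrt(np.sum((a - b) ** 2)))


def build_similarity(points) -> SimilarityMatrix:
    """Pairwise Euclidean distance matrix of all points in a cluster."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) == 0:
        raise ValueError("cannot build a similarity matrix for zero points")
    return SimilarityMatrix(cdist(pts, pts))


def agglomerate(
    points, d_stop: float, linkage: str = "single"
) -> TillerCountPerCluster:
    """Agglomerative clustering with a distance stop condition.

    Starting from singleton classes, repeatedly merges the pair of classes
    with the smallest inter-class distance while that distance is at most
    ``d_stop`` (inclusive); stops when the minimum exceeds ``d_stop`` or one
    class remains.  Equal merge distances are resolved toward the
    lexicographically smallest pair of class ids, making the procedure fully
    deterministic.  Inter-class distances follow the chosen linkage via
    Lance-Williams updates.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    N = len(pts)
    if N == 0:
        raise ValueError("cannot cluster zero points")
    if d_stop <= 0:
        raise ValueError("d_stop must be positive")
    if linkage not in _LINKAGES:
        raise ValueError(f"linkage must be one of {_LINKAGES}")

    # class id = smallest original point index in the class; merging into
    # the smaller id keeps ids stable and makes the tie-break well defined.
    # Inactive classes are masked in place with +inf, so each iteration is a
    # single argmin over the (symmetric) working matrix: the first (row-major)
    # occurrence of the minimum is the lexicographically smallest pair.
    work = cdist(pts, pts)
    np.fill_diagonal(work, np.inf)
    active = np.ones(N, dtype=bool)
    n_active = N
    sizes = np.ones(N, dtype=np.int64)
    owner = np.arange(N)  # class id per point
    merges: list[tuple[int, int, float]] = []

    while n_active > 1:
        flat = int(np.argmin(work))
        i, j = divmod(flat, N)
        dmin = work[i, j]
        if not np.isfinite(dmin) or dmin > d_stop:
            break
        merges.append((int(i), int(j), float(dmin)))
        # Lance-Williams update of distances to the merged class (id i)
        di, dj = work[i], work[j]
        if linkage == "single":
            new = np.minimum(di, dj)
        elif linkage == "complete":
            new = np.maximum(di, dj)
        else:  # average
            new = (sizes[i] * di + sizes[j] * dj) / (sizes[i] + sizes[j])
        work[i, :] = new
        work[:, i] = new
        work[i, i] = np.inf
        work[j, :] = np.inf
        work[:, j] = np.inf
        active[j] = False
        n_active -= 1
        sizes[i] += sizes[j]
        owner[owner == j] = i

    kept = np.flatnonzero(active)
    relabel = {cid: k for k, cid in enumerate(kept)}
    labels = np.array([relabel[c] for c in owner], dtype=np.int64)
    return TillerCountPerCluster(
        cluster_id=-1,
        tiller_count=int(len(kept)),
        labels=labels,
        dendrogram=Dendrogram(merges=merges, leaf_count=N),
    )


def count_tillers_in_cluster(
    segment: ClusterSegment, config: HCConfig | None = None
) -> TillerCountPerCluster:
    """Count the tillers within one AL cluster segment.

    By default only stem-zone points (layers below the separation layer)
    are clustered; feeding leaf points recreates the leaf-as-tiller
    overcounting the method is designed to avoid.
    """
    cfg = config or HCConfig()
    if cfg.use_points == "stem_only":
        mask = segment.stem_mask
    else:
        mask = np.ones(len(segment.points), dtype=bool)
    pts = segment.points[mask]
    if len(pts) == 0:
        raise ValueError(
            f"cluster {segment.cluster_id}: no "
            f"{'stem-zone' if cfg.use_points == 'stem_only' else ''} points to cluster"
        )
    result = agglomerate(pts, cfg.d_stop, cfg.linkage)
    result.cluster_id = segment.cluster_id
    result.point_index = segment.point_index[mask]
    return result
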