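"""Adaptive layering (AL): segment a wheat row into clusters by height slicing.

The algorithm exploits a structural property of a drilled wheat row: leaves
overlap along the row and project to a nearly continuous band on the ground
plane, while stems are discontinuous because of the interspaces between
densely aggregated groups of plants ("wheat clusters").  The row is sliced
into ``n`` equal-height layers (layer 1 at the top); each adjacent pair
(leaf layer ``i``, stem layer ``i+1``) is projected onto the XOY plane and
binned along X.  Bins holding enough stem-layer points are "mixed", bins
holding only leaf-layer points are "continuous leaf"; a run of mixed bins
flanked by leaf gaps is one cluster.  The pair maximising the cluster count
defines the separation between canopy (leaf) and stem zone, and its mixed
runs become the output segments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .io_preprocess import RowCloud

__all__ = [
    "ALConfig",
    "LayerStack",
    "PairProjection",
    "ClusterSegment",
    "ALResult",
    "layer_row",
    "project_pair",
    "count_clusters",
    "mixed_runs",
    "run_al",
    "select_n",
    "EMPTY",
    "LEAF_ONLY",
    "MIXED",
]

# bin states for the projected leaf/stem pair
EMPTY, LEAF_ONLY, MIXED = 0, 1, 2
_STATE_NAMES = {EMPTY: "empty", LEAF_ONLY: "leaf_only", MIXED: "mixed"}


@dataclass
class ALConfig:
    """Tunable parameters of the adaptive layering step.

    n
        Number of height layers (>= 5 so at least two leaf/stem pairs exist).
    bin_width
        X discretisation of the ground-plane projection, meters.
    min_pts_mixed
        Minimum stem-layer points for a bin to count as "mixed"; guards
        against a single stray point creating a spurious stem part.
    max_empty_gap
        Empty-bin gaps strictly shorter than this (in bins) are bridged when
        delimiting mixed runs, so sparse sampling does not split a part.
    z_min
        Optional height crop (meters) dropping residual ground returns
        before the plant height H is computed.
    """

    n: int = 10
    bin_width: float = 0.01
    min_pts_mixed: int = 3
    max_empty_gap: int = 2
    z_min: float = 0.02

    def __post_init__(self) -> None:
        if self.n < 5:
            raise ValueError("n must be >= 5 (need n-3 >= 2 layer pairs)")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.min_pts_mixed < 1:
            raise ValueError("min_pts_mixed must be >= 1")


@dataclass
class LayerStack:
    """Assignment of row points to ``n`` equal-height layers, top to bottom.

    ``layer_index`` holds 1..n per point (1 = top layer); 0 marks points
    cropped away below ``z_min``.  Layers 1 and n are excluded from every
    leaf/stem pair evaluation.
    """

    n: int
    layer_index: np.ndarray
    H: float
    layer_boundaries: np.ndarray  # n+1 z-values, descending from z_max to z_crop

    def in_layer(self, i: int) -> np.ndarray:
        return self.layer_index == i

    @property
    def excluded_layers(self) -> tuple[int, int]:
        return (1, self.n)


@dataclass
class PairProjection:
    """Ground-plane projection of one leaf/stem layer pair, binned along X."""

    leaf_layer: int
    stem_layer: int
    bin_states: np.ndarray  # int array over X bins, values EMPTY/LEAF_ONLY/MIXED
    bin_edges: np.ndarray  # len(bin_states)+1 ascending x-values
    bin_width: float
    max_empty_gap: int = 2

    def runs(self) -> list[tuple[str, int]]:
        """Run-length encoding of the bin states as (state_name, length)."""
        out: list[tuple[str, int]] = []
        for state, idx in _rle(self.bin_states):
            out.append((_STATE_NAMES[state], len(idx)))
        return out


@dataclass
class ClusterSegment:
    """One wheat cluster: an X interval plus its member points of the row."""

    cluster_id: int
    x_interval: tuple[float, float]
    point_index: np.ndarray  # indices into the source RowCloud
    points: np.ndarray  # (m, 3) member coordinates
    layer_index: np.ndarray  # per-member layer assignment
    stem_mask: np.ndarray  # per-member: True for stem-zone points
    source_pair: tuple[int, int]

    @property
    def stem_points(self) -> np.ndarray:
        return self.points[self.stem_mask]


@dataclass
class ALResult:
    """Output of the adaptive layering step for one row."""

    T_per_pair: dict[tuple[int, int], int]
    separation_layer: int  # winning leaf layer index
    clusters: list[ClusterSegment]
    stack: LayerStack
    config: ALConfig

    @property
    def cluster_count(self) -> int:
        return len(self.clusters)


class NoStemsError(RuntimeError):
    """Raised when no leaf/stem pair produces any cluster ("no stems detected")."""


def _rle(states: np.ndarray) -> Iterator[tuple[int, np.ndarray]]:
    """Yield (state, indices) for each maximal run of equal bin states."""
    states = np.asarray(states)
    if states.size == 0:
        return
    change = np.flatnonzero(np.diff(states)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [states.size]])
    for s, e in zip(starts, ends):
        yield int(states[s]), np.arange(s, e)


def layer_row(row: RowCloud, n: int, z_min: float = 0.0) -> LayerStack:
    """Slice a row into ``n`` equal-height layers between z_min-crop and the top.

    The plant height H is ``max z - min z`` over the (optionally cropped)
    points.  A point exactly on a layer boundary goes to the upper
    (smaller-index) layer; the global minimum-z point goes to layer ``n``.
    """
    if n < 5:
        raise ValueError("n must be >= 5")
    z = row.points[:, 2]
    kept = z >= z_min
    if not kept.any():
        raise ValueError(f"no points at or above z_min={z_min}")
    z_lo = float(z[kept].min())
    z_hi = float(z[kept].max())
    H = z_hi - z_lo
    if H <= 0:
        raise ValueError("degenerate row: all points at the same height")
    thickness = H / n
    idx = np.zeros(len(row), dtype=np.int64)
    # ceil((z_hi - z)/t): boundary points land on the upper layer; the small
    # epsilon keeps points that sit exactly on a boundary from being pushed
    # down by floating-point round-off
    raw = np.ceil((z_hi - z[kept]) / thickness - 1e-9)
    idx[kept] = np.clip(raw, 1, n).astype(np.int64)
    boundaries = z_hi - thickness * np.arange(n + 1)
    return LayerStack(n=n, layer_index=idx, H=H, layer_boundaries=boundaries)


def project_pair(
    stack: LayerStack,
    row: RowCloud,
    leaf_layer: int,
    bin_width: float = 0.01,
    min_pts_mixed: int = 3,
    max_empty_gap: int = 2,
) -> PairProjection:
    """Project one leaf/stem layer pair onto the ground plane and bin along X.

    The stem layer is ``leaf_layer + 1``.  A bin is *mixed* when it holds at
    least ``min_pts_mixed`` stem-layer points, *leaf_only* when it holds at
    least one leaf-layer point but fewer stem points than that, and *empty*
    otherwise.  Only X/Y survive the projection; binning uses X because the
    row runs along X.
    """
    if not (2 <= leaf_layer <= stack.n - 2):
        raise ValueError(
            f"leaf_layer must be in [2, {stack.n - 2}], got {leaf_layer} "
            "(layers 1 and n are excluded)"
        )
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    stem_layer = leaf_layer + 1
    x = row.points[:, 0]
    analysed = stack.layer_index > 0
    x_lo, x_hi = float(x[analysed].min()), float(x[analysed].max())
    n_bins = max(1, math.ceil((x_hi - x_lo) / bin_width)) if x_hi > x_lo else 1
    edges = x_lo + bin_width * np.arange(n_bins + 1)
    edges[-1] = max(edges[-1], x_hi)  # last bin absorbs the right extreme

    leaf_x = x[stack.in_layer(leaf_layer)]
    stem_x = x[stack.in_layer(stem_layer)]
    leaf_counts, _ = np.histogram(leaf_x, bins=edges)
    stem_counts, _ = np.histogram(stem_x, bins=edges)

    states = np.full(n_bins, EMPTY, dtype=np.int8)
    states[leaf_counts >= 1] = LEAF_ONLY
    states[stem_counts >= min_pts_mixed] = MIXED
    return PairProjection(
        leaf_layer=leaf_layer,
        stem_layer=stem_layer,
        bin_states=states,
        bin_edges=edges,
        bin_width=bin_width,
        max_empty_gap=max_empty_gap,
    )


def mixed_runs(states: np.ndarray, max_empty_gap: int = 2) -> list[tuple[int, int]]:
    """Maximal runs of mixed bins as (start, stop) half-open bin indices.

    Empty-bin gaps strictly shorter than ``max_empty_gap`` between two mixed
    runs are bridged (the runs merge); any leaf_only bin separates runs.
    """
    runs: list[tuple[int, int]] = []
    for state, idx in _rle(states):
        if state == MIXED:
            start, stop = int(idx[0]), int(idx[-1]) + 1
            if runs and _bridgeable(states, runs[-1][1], start, max_empty_gap):
                runs[-1] = (runs[-1][0], stop)
            else:
                runs.append((start, stop))
    return runs


def _bridgeable(states: np.ndarray, prev_stop: int, start: int, max_gap: int) -> bool:
    gap = states[prev_stop:start]
    return 0 < len(gap) < max_gap and bool(np.all(gap == EMPTY))


def count_clusters(proj: PairProjection) -> int:
    """Number of wheat clusters seen by one layer pair: its count of mixed runs.

    Equivalent to the criterion "a continuous leaf part between two adjacent
    mixed parts adds one cluster": g eligible gaps between mixed runs imply
    g + 1 runs.  Rows with no mixed bin yield 0.
    """
    return len(mixed_runs(proj.bin_states, proj.max_empty_gap))


def run_al(row: RowCloud, config: ALConfig | None = None) -> ALResult:
    """Run the full adaptive layering step on one row.

    Evaluates all ``n - 3`` leaf/stem pairs (leaf layer i = 2..n-2), picks
    the pair with the largest cluster count (tie: largest leaf index, i.e.
    deepest in the canopy) and materialises its mixed runs as
    :class:`ClusterSegment` objects.  Each segment's interval spans its mixed
    run extended to the midpoints of the flanking gaps (the outermost
    segments extend to the row ends), so every analysed point belongs to
    exactly one segment.  Points in layers below the winning leaf layer are
    flagged as stem-zone points.
    """
    cfg = config or ALConfig()
    stack = layer_row(row, cfg.n, cfg.z_min)

    projections: dict[int, PairProjection] = {}
    T: dict[tuple[int, int], int] = {}
    for i in range(2, stack.n - 1):
        proj = project_pair(
            stack, row, i, cfg.bin_width, cfg.min_pts_mixed, cfg.max_empty_gap
        )
        projections[i] = proj
        T[(i, i + 1)] = count_clusters(proj)

    best = max(T.values())
    if best == 0:
        raise NoStemsError(
            "no stems detected: every leaf/stem pair produced zero clusters"
        )
    # tie-break toward the deepest tied pair: everything above the winning
    # leaf layer is treated as leaf, so picking the shallowest tied pair
    # would sweep canopy layers into the stem zone and count leaves as
    # tillers whenever a canopy pair ties the stem pairs (e.g. a single
    # isolated plant, where every pair sees one cluster)
    sep = max(i for (i, _), t in T.items() if t == best)
    proj = projections[sep]
    runs = mixed_runs(proj.bin_states, cfg.max_empty_gap)
    edges = proj.bin_edges

    # segment boundaries at the midpoints of the gaps between mixed runs
    cuts = [-np.inf]
    for (_, stop_a), (start_b, _) in zip(runs, runs[1:]):
        cuts.append(0.5 * (edges[stop_a] + edges[start_b]))
    cuts.append(np.inf)

    x = row.points[:, 0]
    analysed = stack.layer_index > 0
    x_lo, x_hi = float(x[analysed].min()), float(x[analysed].max())
    stem_zone = stack.layer_index > sep  # strictly below the winning leaf layer
    clusters: list[ClusterSegment] = []
    for cid, (_, lo, hi) in enumerate(zip(runs, cuts, cuts[1:])):
        member = analysed & (x >= lo) & (x < hi) if hi < np.inf else analysed & (x >= lo)
        idx = np.flatnonzero(member)
        clusters.append(
            ClusterSegment(
                cluster_id=cid,
                x_interval=(float(max(lo, x_lo)), float(min(hi, x_hi))),
                point_index=idx,
                points=row.points[idx],
                layer_index=stack.layer_index[idx],
                stem_mask=stem_zone[idx],
                source_pair=(sep, sep + 1),
            )
        )
    return ALResult(
        T_per_pair=T, separation_layer=sep, clusters=clusters, stack=stack, config=cfg
    )


def select_n(
    row: RowCloud,
    candidate_ns: list[int],
    expected_density: float,
    config: ALConfig | None = None,
) -> int:
    """Choose the layer count n whose cluster rate best matches planting density.

    Runs the AL step once per candidate and returns the candidate whose
    maximum cluster count per meter of row is closest to
    ``expected_density`` (clusters/m); ties go to the smaller n.  This
    automates the trial-run calibration of n against the known planting
    density.
    """
    if not candidate_ns:
        raise ValueError("candidate_ns must be non-empty")
    cfg = config or ALConfig()
    length = row.row_axis_length
    if length <= 0:
        raise ValueError("row has zero extent along X")
    best_n, best_err = None, np.inf
    for n in sorted(candidate_ns):
        trial = ALConfig(
            n=n,
            bin_width=cfg.bin_width,
            min_pts_mixed=cfg.min_pts_mixed,
            max_empty_gap=cfg.max_empty_gap,
            z_min=cfg.z_min,
        )
        count = run_al(row, trial).cluster_count
        err = abs(count / length - expected_density)
        if err < best_err:
            best_n, best_err = n, err
    return int(best_n)
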