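"""Synthetic TLS-like wheat rows with exact cluster/tiller ground truth.

The generator reproduces the structural premise the layering + clustering
method relies on, not photorealistic plants: stems are slightly tilted,
densely sampled vertical columns grouped into clusters along the row axis;
the canopy above is a closed volume of drooping leaf arcs plus overlapping
filler foliage whose ground-plane projection is continuous along the row
whenever the leaf reach bridges the inter-cluster gaps.  Sensor artefacts
are modelled as uniform noise points in the bounding box and
height-dependent random thinning (occlusion is strongest near the ground,
where laser incidence angles are largest).

Every point carries labels (``cluster_id``, ``tiller_id``,
``kind`` in {stem=0, leaf=1, noise=2}) so each pipeline stage can be scored
against exact truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .io_preprocess import RowCloud, write_cloud

__all__ = [
    "RowScenario",
    "SyntheticRowTruth",
    "generate_row",
    "make_fixture_suite",
    "KIND_STEM",
    "KIND_LEAF",
    "KIND_NOISE",
]

KIND_STEM, KIND_LEAF, KIND_NOISE = 0, 1, 2

# vertical structure as fractions of plant height: stems occupy
# [0, STEM_TOP], the canopy [CANOPY_BOT, 1]; the band between is point-free
# (bare lower internodes at jointing), which keeps leaves out of the stem
# zone that the clustering stage consumes.
STEM_TOP = 0.55
CANOPY_BOT = 0.68
ARC_TIP_MARGIN = 0.04  # arc tips stay this far (xH) above the canopy floor


@dataclass
class RowScenario:
    """Parameters of one synthetic row.

    All lengths in meters.  ``cluster_spacing`` is the mean center-to-center
    spacing of wheat clusters along the row (jittered by
    ``cluster_spacing_jitter`` and clamped so adjacent clusters keep at
    least ``min_cluster_gap`` of stem-free space between their outermost
    tillers).  ``tiller_spread`` is the minimum stem-to-stem separation
    inside a cluster; the default 0.03 keeps distinct tillers farther apart
    than the 2 cm clustering threshold.  ``compactness`` controls stem tilt
    (loose plants lean more, eroding that margin).  ``occlusion`` is an
    optional ``(p_ground, p_top)`` pair: each point is removed with a
    probability interpolated linearly in height.
    """

    row_length: float = 1.0
    cluster_spacing: float = 0.15
    cluster_spacing_jitter: float = 0.02
    tillers_per_cluster: tuple[int, int] = (2, 5)
    tiller_spread: float = 0.03
    plant_height: float = 0.45
    stem_point_density: float = 400.0
    leaf_overlap_reach: float = 0.08
    compactness: str = "compact"
    noise_fraction: float = 0.0
    occlusion: tuple[float, float] | None = None
    min_cluster_gap: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "row_length",
            "cluster_spacing",
            "tiller_spread",
            "plant_height",
            "stem_point_density",
            "leaf_overlap_reach",
            "min_cluster_gap",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.noise_fraction < 1:
            raise ValueError("noise_fraction must be in [0, 1)")
        if self.tiller_spread > self.cluster_spacing:
            raise ValueError(
                "infeasible geometry: tiller_spread exceeds cluster_spacing"
            )
        lo, hi = self.tillers_per_cluster
        if lo < 1 or hi < lo:
            raise ValueError("tillers_per_cluster must be a (lo, hi) range, lo >= 1")
        if self.compactness not in ("compact", "loose"):
            raise ValueError("compactness must be 'compact' or 'loose'")
        if self.occlusion is not None:
            pg, pt = self.occlusion
            if not (0 <= pg <= 1 and 0 <= pt <= 1):
                raise ValueError("occlusion probabilities must be in [0, 1]")


@dataclass
class SyntheticRowTruth:
    """A generated row plus its exact ground truth."""

    cloud: RowCloud
    true_cluster_count: int
    true_tiller_count: int
    scenario: RowScenario


def _stem_tilt(compactness: str) -> float:
    """Maximum horizontal displacement of a stem top relative to its base."""
    return 0.0015 if compactness == "compact" else 0.015


def generate_row(scenario: RowScenario) -> SyntheticRowTruth:
    """Generate one labeled synthetic wheat row (reproducible from its seed)."""
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    H = sc.plant_height
    tilt_max = _stem_tilt(sc.compactness)

    # --- cluster layout along X --------------------------------------------
    lo, hi = sc.tillers_per_cluster
    centers: list[float] = []
    k_tillers: list[int] = []
    extents: list[float] = []
    x = 0.05
    prev_half = 0.0
    while True:
        k = int(rng.integers(lo, hi + 1))
        spread = sc.tiller_spread * (1.0 + 0.1 * rng.random())
        extent = (k - 1) * spread
        if centers:
            spacing = sc.cluster_spacing + rng.uniform(
                -sc.cluster_spacing_jitter, sc.cluster_spacing_jitter
            )
            spacing = max(spacing, prev_half + extent / 2 + sc.min_cluster_gap)
            x = centers[-1] + spacing
        if x + extent / 2 > sc.row_length - 0.03 and centers:
            break
        centers.append(x)
        k_tillers.append(k)
        extents.append(extent)
        prev_half = extent / 2
        if not centers:  # pragma: no cover - defensive
            break

    pts: list[np.ndarray] = []
    cluster_id: list[np.ndarray] = []
    tiller_id: list[np.ndarray] = []
    kind: list[np.ndarray] = []

    def emit(block: np.ndarray, cid: int, tid: int, knd: int) -> None:
        pts.append(block)
        m = len(block)
        cluster_id.append(np.full(m, cid, dtype=np.int64))
        tiller_id.append(np.full(m, tid, dtype=np.int64))
        kind.append(np.full(m, knd, dtype=np.int64))

    # --- stems --------------------------------------------------------------
    tid = 0
    stem_top = STEM_TOP * H
    for cid, (xc, k, extent) in enumerate(zip(centers, k_tillers, extents)):
        spread = extent / (k - 1) if k > 1 else 0.0
        yc = rng.uniform(-0.015, 0.015)
        for j in range(k):
            xb = xc - extent / 2 + j * spread
            yb = yc + rng.uniform(-0.01, 0.01)
            h = stem_top * rng.uniform(0.85, 1.0)
            n_pts = max(4, int(round(h * sc.stem_point_density)))
            # jittered regular spacing keeps vertical gaps well under 2 cm
            z = (np.arange(n_pts) + rng.uniform(0.1, 0.9, n_pts)) * (h / n_pts)
            theta = rng.uniform(0, 2 * np.pi)
            r_tilt = rng.uniform(0.3, 1.0) * tilt_max
            frac = z / h
            jx = np.clip(rng.normal(0, 0.001, n_pts), -0.0025, 0.0025)
            jy = np.clip(rng.normal(0, 0.001, n_pts), -0.0025, 0.0025)
            block = np.column_stack(
                [
                    xb + r_tilt * np.cos(theta) * frac + jx,
                    yb + r_tilt * np.sin(theta) * frac + jy,
                    z,
                ]
            )
            emit(block, cid, tid, KIND_STEM)
            tid += 1

    # --- canopy: drooping leaf arcs ----------------------------------------
    canopy_bot = CANOPY_BOT * H
    tip_floor = (CANOPY_BOT + ARC_TIP_MARGIN) * H
    tid2 = 0
    for cid, (xc, k, extent) in enumerate(zip(centers, k_tillers, extents)):
        spread = extent / (k - 1) if k > 1 else 0.0
        for j in range(k):
            xb = xc - extent / 2 + j * spread
            for direction in (-1.0, 1.0):
                reach = sc.leaf_overlap_reach * rng.uniform(0.7, 1.0)
                ztop = H * rng.uniform(0.9, 1.0)
                ztip = rng.uniform(tip_floor, 0.85 * H)
                n_pts = max(6, int(round(reach / 0.004)))
                t = np.linspace(0, 1, n_pts) + rng.uniform(-0.02, 0.02, n_pts)
                t = np.clip(t, 0, 1)
                block = np.column_stack(
                    [
                        xb + direction * reach * t + rng.normal(0, 0.002, n_pts),
                        rng.uniform(-0.02, 0.02)
                        + rng.normal(0, 0.004, n_pts),
                        ztop - (ztop - ztip) * t**2,
                    ]
                )
                emit(block, cid, tid2, KIND_LEAF)
            tid2 += 1

    # --- canopy: closed-canopy filler foliage -------------------------------
    # a dense lattice per cluster footprint emulating the many overlapping
    # leaves of neighbouring plants; makes the upper canopy's ground-plane
    # projection continuous, which is the premise the layering step exploits
    dx = dz = 0.003
    for cid, (xc, extent) in enumerate(zip(centers, extents)):
        half = extent / 2 + sc.leaf_overlap_reach
        xs = np.arange(xc - half, xc + half + dx / 2, dx)
        zs = np.arange(canopy_bot, H - 1e-9, dz)
        gx, gz = np.meshgrid(xs, zs)
        m = gx.size
        block = np.column_stack(
            [
                gx.ravel() + rng.uniform(-0.0005, 0.0005, m),
                rng.uniform(-0.03, 0.03, m),
                gz.ravel() + rng.uniform(-0.0005, 0.0005, m),
            ]
        )
        emit(block, cid, -1, KIND_LEAF)

    points = np.vstack(pts)
    labels = {
        "cluster_id": np.concatenate(cluster_id),
        "tiller_id": np.concatenate(tiller_id),
        "kind": np.concatenate(kind),
    }

    # --- sensor noise -------------------------------------------------------
    if sc.noise_fraction > 0:
        n_signal = len(points)
        n_noise = int(round(sc.noise_fraction / (1 - sc.noise_fraction) * n_signal))
        lo_xyz = points.min(axis=0)
        hi_xyz = points.max(axis=0)
        noise = rng.uniform(lo_xyz, hi_xyz, size=(n_noise, 3))
        noise[:, 2] = rng.uniform(0, H, n_noise)
        points = np.vstack([points, noise])
        for name, fill in (("cluster_id", -1), ("tiller_id", -1), ("kind", KIND_NOISE)):
            labels[name] = np.concatenate(
                [labels[name], np.full(n_noise, fill, dtype=np.int64)]
            )

    # --- occlusion: height-dependent thinning -------------------------------
    if sc.occlusion is not None:
        p_ground, p_top = sc.occlusion
        frac = np.clip(points[:, 2] / H, 0, 1)
        p_remove = p_ground + (p_top - p_ground) * frac
        keep = rng.random(len(points)) >= p_remove
        points = points[keep]
        labels = {k: v[keep] for k, v in labels.items()}

    points[:, 2] = np.maximum(points[:, 2], 0.0)
    cloud = RowCloud(points, labels, ground_z=0.0)
    stem = labels["kind"] == KIND_STEM
    return SyntheticRowTruth(
        cloud=cloud,
        true_cluster_count=int(np.unique(labels["cluster_id"][stem]).size),
        true_tiller_count=int(np.unique(labels["tiller_id"][stem]).size),
        scenario=sc,
    )


def _suite_scenarios(base_seed: int) -> dict[str, RowScenario]:
    """The fixed fixture battery: density x plant type, plus noise,
    occlusion and an unbridged-gap stress case."""
    return {
        "dense_compact": RowScenario(cluster_spacing=0.12, seed=base_seed + 1),
        "dense_loose": RowScenario(
            cluster_spacing=0.12, compactness="loose", seed=base_seed + 2
        ),
        "sparse_compact": RowScenario(cluster_spacing=0.20, seed=base_seed + 3),
        "sparse_loose": RowScenario(
            cluster_spacing=0.20, compactness="loose", seed=base_seed + 4
        ),
        "low_noise": RowScenario(noise_fraction=0.01, seed=base_seed + 5),
        "high_noise": RowScenario(noise_fraction=0.02, seed=base_seed + 6),
        "occluded": RowScenario(occlusion=(0.4, 0.05), seed=base_seed + 7),
        "narrow_leaves": RowScenario(
            cluster_spacing=0.22, leaf_overlap_reach=0.03, seed=base_seed + 8
        ),
        "tight_tillers": RowScenario(tiller_spread=0.018, seed=base_seed + 9),
    }


def make_fixture_suite(out_dir, base_seed: int = 0) -> dict:
    """Write the fixed battery of labeled PLY fixtures plus a truth manifest.

    Returns the manifest (also written as ``manifest.json``): per scenario
    the file name, seed, truth counts and the generating parameters.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict] = {}
    for name, sc in _suite_scenarios(base_seed).items():
        truth = generate_row(sc)
        fname = f"{name}.ply"
        write_cloud(truth.cloud, out_dir / fname)
        params = asdict(sc)
        params["tillers_per_cluster"] = list(sc.tillers_per_cluster)
        if sc.occlusion is not None:
            params["occlusion"] = list(sc.occlusion)
        manifest[name] = {
            "file": fname,
            "seed": sc.seed,
            "true_cluster_count": truth.true_cluster_count,
            "true_tiller_count": truth.true_tiller_count,
            "n_points": len(truth.cloud),
            "scenario": params,
        }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
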