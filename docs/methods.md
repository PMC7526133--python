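# Methods

## Problem setting and assumptions

The package estimates the number of tillers in a single drilled wheat row
from a terrestrial LiDAR point cloud. The input row is assumed to be
registered and oriented (the package provides a rigid re-orientation
helper): X runs along the row, Y across it, Z is plant height with the soil
at z = 0. The method targets the tillering and jointing stages, where a
"stem" means the trunk of an aboveground tiller excluding leaves.

Two structural assumptions drive everything:

* along the row, leaves of neighbouring plants overlap, so the canopy's
  ground-plane projection is (nearly) continuous, while stems occur in
  separated groups — *wheat clusters* of densely aggregated plants;
* within a cluster, distinct tillers are at least ~2 cm apart, while the
  points of one tiller are much closer together than that.

The first assumption powers the cluster segmentation (adaptive layering),
the second the per-cluster tiller count (threshold-stopped agglomerative
clustering).

## Adaptive layering

The row is cut into `n` equal-height slabs between the (optionally
ground-cropped) minimum and maximum height; slab 1 is at the top. Slabs 1
and `n` are never evaluated — the canopy top is fragmentary and the bottom
slab collects ground returns. For each adjacent pair (leaf layer `i`, stem
layer `i+1`), `i = 2..n-2`, both slabs are projected to the ground plane
and binned along X:

* a bin with ≥ `min_pts_mixed` stem-layer points is **mixed**;
* a bin with ≥ 1 leaf-layer point (and fewer stem points) is **leaf-only**;
* anything else is **empty**.

The cluster count of the pair is the number of maximal mixed runs, which
equals "continuous leaf parts between two adjacent mixed parts" + 1
whenever any mixed bin exists. Counting mixed runs makes the edge cases
(leaf parts at the row ends, gaps that are empty rather than leaf-covered)
well-defined. Empty gaps strictly shorter than `max_empty_gap` bins are
bridged so that sparse laser sampling cannot split a physical stem part.

The pair with the largest count wins; everything above the winning leaf
layer is labeled leaf, everything below it stem. **Ties break to the
deepest tied pair.** This choice matters: for a row with a single cluster
every pair sees one cluster, and breaking ties toward the canopy top would
place the entire canopy in the stem zone, after which the clustering stage
would count leaves as tillers. Breaking ties downward always leaves the
canopy out of the stem zone and is the conservative option under the
method's own assumptions. The winning pair's mixed runs, extended to the
midpoints of the gaps between them (outermost runs extend to the row
ends), become the cluster segments; every analysed point belongs to
exactly one segment.

Only the winning pair's projection is reused for the output (no aggregate
re-projection of all leaf/stem layers); the alternative reading is not
silently substituted.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `n` | 10 | height layers; ≥ 5 so that ≥ 2 pairs exist |
| `bin_width` | 0.01 m | X discretisation of the projection |
| `min_pts_mixed` | 3 | stem points needed for a mixed bin; rejects stray points |
| `max_empty_gap` | 2 bins | empty gaps shorter than this are bridged |
| `z_min` | 0.02 m | ground-return crop before computing plant height |

`select_n` automates the choice of `n` when a planting density
(clusters/m) is known: it evaluates candidate values and keeps the one
whose cluster rate is closest to that density, ties to the smaller `n`.

## Hierarchical clustering

Within one segment, the stem-zone points (default; an `all` mode exists
for experimentation) are clustered agglomeratively: starting from
singletons, the pair of classes with the smallest inter-class distance is
merged while that distance is ≤ `d_stop`; linkage is `single` by default
(`complete` and `average` via Lance–Williams updates are available). Equal
merge distances resolve toward the lexicographically smallest class-id
pair, making the procedure fully deterministic. The stop rule is
inclusive: a distance exactly equal to `d_stop` still merges.

`d_stop` defaults to 0.02 m — the assumed minimum spacing of field wheat
tillers. Single linkage is the default because merging "the nearest two
units" is exactly single linkage at the first merge, and because the class
count at the cut then equals the number of connected components of the
graph joining points within `d_stop` — an identity the test suite verifies
against brute-force graph traversal. The threshold is deliberately exposed
(`sweep_d`) since the optimal value shifts with growth stage and planting
density; under single linkage the row count is provably non-increasing
in `d_stop`.

Leaf points are excluded from the count by default because leaves sit
farther than `d_stop` from the stem bundle and would each found spurious
classes — the leaf-as-tiller overcounting failure mode the layering stage
exists to prevent.

The distance-matrix implementation is O(N²) memory and roughly O(N³) time
per segment; segments produced by the layering stage are small (tens to a
few hundred points), where this is faster and simpler than a nearest-
neighbour-chain scheme.

## Plot density and evaluation

`T_plot = T_row · r / S` converts the per-row count to tillers/m² exactly
(no rounding), with `r` rows per plot and area `S` in m². One row per plot
is counted, mirroring the usual sampling protocol; multi-row averaging is
left to the caller.

Agreement metrics: RMSE, R² and RRMSE (%). Two published denominator
conventions exist: R² is conventionally computed against the *reference*
mean and RRMSE against the *mean reference*, but typeset variants with the
predicted mean (R²) and the mean signed difference (RRMSE) also occur.
The conventional forms are the defaults; the alternatives are implemented
behind `variant="as_printed"` flags and recorded in the result object, so
either convention can be reproduced and compared.

## Synthetic rows

The generator reproduces the structural premises, not botany:

* **stems** — per tiller, a vertical column of points at ~2.5 mm vertical
  spacing with millimetre lateral jitter, occupying the lower 55% of the
  plant height, slightly tilted (compact plants ≤ 1.5 mm top displacement,
  loose plants ≤ 15 mm — the latter deliberately erodes the 2 cm margin);
* **clusters** — tiller bases placed ≥ `tiller_spread` (default 3 cm)
  apart; cluster centers spaced `cluster_spacing` ± jitter along the row,
  clamped so adjacent clusters keep ≥ 5 cm of stem-free gap;
* **canopy** — two drooping quadratic leaf arcs per tiller reaching
  `leaf_overlap_reach` toward the neighbours, plus a dense filler lattice
  over each cluster's foliage footprint emulating the closed upper canopy
  of overlapping leaves. The canopy occupies the upper ~32% of the height;
  the band between stem tops and canopy floor is point-free, emulating the
  bare lower internodes of a jointing-stage stand. When
  `leaf_overlap_reach` is at least half the cluster gap the canopy
  projection is gap-free along X while the stem projection has exactly
  (clusters − 1) gaps — precisely the premise of the layering criterion;
* **noise** — a chosen fraction of points uniform in the bounding box;
* **occlusion** — height-dependent random thinning (strongest near the
  ground, where TLS incidence angles are largest); no ray-casting.

Default scale: a 1 m row (the usual manual-count section), 0.45 m plant
height, ~6 clusters of 2–5 tillers (≈ 20 tillers/row), 400 points per
meter of stem. These densities are sparser than a real high-density stand;
the generator is built to make ground truth exact and the method's
assumptions controllable, not to reproduce field point statistics. Passing
tests therefore demonstrate algorithmic correctness under the method's
stated assumptions — they do not certify accuracy on real field scans,
where occlusion and registration noise dominate.

Every cloud carries per-point labels (`cluster_id`, `tiller_id`, `kind` ∈
{stem, leaf, noise}); truth counts are recomputed from the surviving
labels after thinning. Everything is reproducible from the scenario seed.
`make_fixture_suite` writes a fixed battery of nine scenarios (dense ×
sparse, compact × loose, two noise levels, occlusion, unbridged gaps and
sub-threshold tiller spacing) with a JSON truth manifest.

## Numerical choices and degenerate inputs

* Layer assignment: a point exactly on a slab boundary belongs to the
  upper slab (with a 1e-9 relative epsilon against round-off); the
  global minimum goes to slab `n`. A height-degenerate (flat) row is an
  error, as is `n < 5`.
* Projection bins are half-open on the right; the last bin absorbs the
  row's right extreme.
* A row in which no layer pair yields a single mixed bin raises
  "no stems detected" rather than returning zero.
* The statistical outlier filter (mean distance to k nearest neighbours
  vs. global mean + `std_mult`·sd) is **off by default** — field practice
  removes floating noise before analysis — and is the pipeline's intended
  noise-handling step when scans are noisy; with uniform sensor noise,
  `k = 8, std_mult = 2` removes isolated points without touching the
  canopy.
* File I/O: PLY ascii and binary little-endian with integer label
  channels, LAS 1.x point formats 0–3 (read-only; compressed LAZ is
  rejected with a clear message), XYZ CSV with or without header. Unit
  conversion (m/cm/mm) happens once at ingestion; everything internal is
  meters. Round-trips preserve coordinates to < 1e-6 m.

## Problem sizes used in the bundled checks

The test-suite and the acceptance script run on synthetic rows of roughly
20–30 k points (seconds per row): 50 clean rows for exact recovery, 20
noisy rows for the robustness rate, 500 random point sets (N ≤ 12) for the
clustering oracle, 1000 random bin sequences for the run-count oracle, the
9-scenario fixture battery for the d-sweep, and a 12-level planting-density
gradient for the agreement metrics.

## Known limitations

* The separation layer is global per row; strongly varying canopy height
  along a row can misplace it locally.
* Curved rows, multi-row scenes and terrain relief are out of scope; the
  row frame is a rigid transform with a flat ground plane.
* The 2 cm threshold is a biological prior, not estimated from data;
  dense stands where tillers stand closer will be undercounted (the
  `tight_tillers` fixture demonstrates this deliberately).
* Real TLS artefacts — registration error, multi-echo returns, wind
  motion — are only coarsely emulated by uniform noise and thinning.
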