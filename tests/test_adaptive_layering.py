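import numpy as np
import pytest

from tillerscan import (
    ALConfig,
    NoStemsError,
    RowCloud,
    count_clusters,
    layer_row,
    project_pair,
    run_al,
    select_n,
)
from tillerscan.adaptive_layering import EMPTY, LEAF_ONLY, MIXED, PairProjection, mixed_runs

from conftest import build_handmade_row


def _column(x, z_lo, z_hi, dz=0.002, y=0.0):
    z = np.arange(z_lo, z_hi, dz)
    return np.column_stack([np.full_like(z, x), np.full_like(z, y), z])


class TestLayerRow:
    def test_hand_computed_slabs(self):
        z = np.array([0.05, 0.15, 0.25, 0.35, 0.45])
        cloud = RowCloud(np.column_stack([np.arange(5.0) * 0.1, np.zeros(5), z]))
        stack = layer_row(cloud, n=5, z_min=0.0)
        assert stack.H == pytest.approx(0.4)
        np.testing.assert_array_equal(stack.layer_index, [5, 4, 3, 2, 1])

    def test_boundary_point_goes_to_upper_layer(self):
        # boundaries at z = 0.4, 0.3, 0.2, 0.1, 0.0 for H=0.4, n=4... use n=5
        z = np.array([0.0, 0.32, 0.4])  # H=0.4, thickness 0.08; 0.32 on boundary 1|2
        cloud = RowCloud(np.column_stack([z * 0 + np.arange(3) * 0.1, np.zeros(3), z]))
        stack = layer_row(cloud, n=5, z_min=0.0)
        assert stack.layer_index[1] == 1
        assert stack.layer_index[0] == 5  # global minimum to the bottom layer

    def test_flat_cloud_rejected(self):
        cloud = RowCloud(np.column_stack([np.arange(3.0), np.zeros(3), np.full(3, 0.2)]))
        with pytest.raises(ValueError):
            layer_row(cloud, n=5)

    def test_small_n_rejected(self, handmade_row):
        with pytest.raises(ValueError):
            layer_row(handmade_row[0], n=4)

    def test_partition_property(self, clean_truth):
        stack = layer_row(clean_truth.cloud, n=10, z_min=0.02)
        analysed = stack.layer_index > 0
        counts = np.bincount(stack.layer_index[analysed], minlength=stack.n + 1)[1:]
        assert counts.sum() == analysed.sum()
        assert np.all((stack.layer_index >= 0) & (stack.layer_index <= stack.n))


class TestProjectPair:
    @staticmethod
    def _pair_cloud():
        # z span [0, 0.5], n=5 layers of 0.1: layer 2 = (0.3, 0.4], layer 3 = (0.2, 0.3]
        pts = [np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 0.5]])]  # pin the extent
        xs = np.arange(0.0, 0.601, 0.01)
        pts.append(np.column_stack([xs, np.zeros_like(xs), np.full_like(xs, 0.35)]))
        for x_stem in (0.10, 0.50):
            pts.append(np.array([[x_stem, 0.0, 0.25]]))
        return RowCloud(np.vstack(pts))

    def test_two_mixed_runs_one_leaf_gap(self):
        cloud = self._pair_cloud()
        stack = layer_row(cloud, n=5, z_min=0.0)
        proj = project_pair(stack, cloud, leaf_layer=2, bin_width=0.02, min_pts_mixed=1)
        assert proj.stem_layer == 3
        states = [s for s, _ in proj.runs()]
        assert states.count("mixed") == 2
        mixed_blocks = mixed_runs(proj.bin_states, proj.max_empty_gap)
        assert len(mixed_blocks) == 2
        # exactly one leaf-only run separates the two mixed runs
        inner = proj.bin_states[mixed_blocks[0][1] : mixed_blocks[1][0]]
        assert np.all(inner == LEAF_ONLY)

    def test_no_stem_points_no_mixed_bins(self):
        cloud = self._pair_cloud()
        stack = layer_row(cloud, n=5, z_min=0.0)
        proj = project_pair(stack, cloud, leaf_layer=3, bin_width=0.02, min_pts_mixed=1)
        assert not np.any(proj.bin_states == MIXED)

    def test_stems_everywhere_all_mixed(self):
        xs = np.arange(0.0, 0.5, 0.005)
        pts = np.vstack(
            [
                np.column_stack([xs, np.zeros_like(xs), np.full_like(xs, 0.25)]),
                [[0.0, 0.0, 0.0], [0.0, 0.0, 0.5]],
            ]
        )
        cloud = RowCloud(pts)
        stack = layer_row(cloud, n=5, z_min=0.0)
        proj = project_pair(stack, cloud, leaf_layer=2, bin_width=0.02, min_pts_mixed=1)
        nonempty = proj.bin_states != EMPTY
        assert np.all(proj.bin_states[nonempty] == MIXED)

    def test_leaf_layer_out_of_range(self):
        cloud = self._pair_cloud()
        stack = layer_row(cloud, n=5, z_min=0.0)
        for bad in (1, 4, 5):
            with pytest.raises(ValueError):
                project_pair(stack, cloud, leaf_layer=bad)


def _proj(states):
    states = np.asarray(states, dtype=np.int8)
    edges = 0.01 * np.arange(len(states) + 1)
    return PairProjection(2, 3, states, edges, 0.01)


class TestCountClusters:
    @pytest.mark.parametrize(
        "states,expected",
        [
            ([MIXED], 1),
            ([MIXED, LEAF_ONLY, MIXED, LEAF_ONLY, MIXED], 3),
            ([LEAF_ONLY, LEAF_ONLY, LEAF_ONLY], 0),
            ([], 0),
            ([EMPTY, MIXED, EMPTY, MIXED, EMPTY], 1),  # 1-bin gap bridged
            ([MIXED, EMPTY, EMPTY, MIXED], 2),  # 2-bin gap not bridged
            ([MIXED, EMPTY, LEAF_ONLY, MIXED], 2),  # leaf breaks the bridge
        ],
    )
    def test_examples(self, states, expected):
        assert count_clusters(_proj(states)) == expected

    def test_matches_independent_scan(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            states = rng.integers(0, 3, size=rng.integers(1, 40))
            got = count_clusters(_proj(states))
            assert got == _oracle_count(states, max_gap=2)


def _oracle_count(states, max_gap):
    """Independent run scan: a mixed bin starts a new cluster unless reached
    from the previous mixed bin across only empty bins, fewer than max_gap."""
    count = 0
    last_mixed = None
    leaf_between = False
    for i, s in enumerate(states):
        if s == MIXED:
            if last_mixed is None or leaf_between or (i - last_mixed - 1) >= max_gap:
                count += 1
            last_mixed = i
            leaf_between = False
        elif s == LEAF_ONLY:
            leaf_between = True
    return count


class TestRunAL:
    def test_three_isolated_plants(self):
        cloud, _ = build_handmade_row(
            cluster_centers=(0.10, 0.35, 0.60),
            tillers_per_cluster=(1, 1, 1),
            leaf_span=(0.0, 0.70),
        )
        result = run_al(cloud, ALConfig(n=8, z_min=0.0))
        assert result.cluster_count == 3
        assert len(result.clusters) == 3
        # each true plant position falls inside exactly one segment interval
        intervals = [c.x_interval for c in result.clusters]
        for x_plant in (0.10, 0.35, 0.60):
            assert sum(lo <= x_plant <= hi for lo, hi in intervals) == 1

    def test_single_plant(self):
        cloud, _ = build_handmade_row(
            cluster_centers=(0.30,),
            tillers_per_cluster=(1,),
            leaf_span=(0.1, 0.5),
        )
        assert run_al(cloud, ALConfig(n=8, z_min=0.0)).cluster_count == 1

    @pytest.mark.parametrize("n", [5, 8, 12])
    def test_pair_count_is_n_minus_3(self, handmade_row, n):
        result = run_al(handmade_row[0], ALConfig(n=n, z_min=0.0))
        assert len(result.T_per_pair) == n - 3
        assert set(result.T_per_pair) == {(i, i + 1) for i in range(2, n - 1)}

    def test_boundary_layers_never_project(self, handmade_row):
        result = run_al(handmade_row[0], ALConfig(n=8, z_min=0.0))
        pairs = set(result.T_per_pair)
        assert all(1 not in pair and result.stack.n not in pair for pair in pairs)

    def test_no_stems_detected(self):
        # sparse scattered points: no bin in any layer reaches min_pts_mixed=3
        xs = np.arange(0.0, 1.0, 0.05)
        zs = np.tile(np.arange(0.05, 0.45, 0.05), len(xs))[: len(xs)]
        cloud = RowCloud(np.column_stack([xs, np.zeros_like(xs), zs]))
        with pytest.raises(NoStemsError):
            run_al(cloud, ALConfig(n=6, z_min=0.0))

    def test_translation_invariance(self, handmade_row):
        cloud, _ = handmade_row
        base = run_al(cloud, ALConfig(z_min=0.0))
        shifted = RowCloud(cloud.points + np.array([3.7, 0.0, 0.0]))
        moved = run_al(shifted, ALConfig(z_min=0.0))
        assert moved.T_per_pair == base.T_per_pair
        assert moved.cluster_count == base.cluster_count

    def test_well_separated_copy_doubles_count(self, handmade_row):
        cloud, _ = handmade_row
        copy = cloud.points + np.array([5.0, 0.0, 0.0])
        doubled = RowCloud(np.vstack([cloud.points, copy]))
        base = run_al(cloud, ALConfig(z_min=0.0))
        both = run_al(doubled, ALConfig(z_min=0.0))
        assert both.cluster_count == 2 * base.cluster_count

    def test_every_analysed_point_in_exactly_one_cluster(self, clean_truth):
        result = run_al(clean_truth.cloud)
        analysed = np.flatnonzero(result.stack.layer_index > 0)
        assigned = np.concatenate([c.point_index for c in result.clusters])
        assert sorted(assigned) == sorted(analysed)
        intervals = sorted(c.x_interval for c in result.clusters)
        for (_, hi), (lo, _) in zip(intervals, intervals[1:]):
            assert hi <= lo  # disjoint

    def test_each_cluster_has_stem_points(self, clean_truth):
        result = run_al(clean_truth.cloud)
        assert all(c.stem_mask.sum() >= 1 for c in result.clusters)


class TestSelectN:
    def test_tie_returns_smallest(self):
        cloud, _ = build_handmade_row(
            cluster_centers=(0.2, 0.6), tillers_per_cluster=(1, 1), leaf_span=(0.0, 0.8)
        )
        # all candidates resolve the same two plants
        n = select_n(cloud, [8, 10, 12], expected_density=2.5, config=ALConfig(z_min=0.0))
        assert n == 8

    def test_picks_density_minimiser(self, clean_truth):
        row = clean_truth.cloud
        density = clean_truth.true_cluster_count / row.row_axis_length
        candidates = [6, 10, 14]
        best = select_n(row, candidates, expected_density=density)
        # exhaustive re-evaluation oracle
        counts = {
            n: run_al(row, ALConfig(n=n)).cluster_count / row.row_axis_length
            for n in candidates
        }
        expected = min(sorted(candidates), key=lambda n: abs(counts[n] - density))
        assert best == expected

    def test_zero_density_prefers_fewest(self, clean_truth):
        row = clean_truth.cloud
        candidates = [6, 10, 14]
        best = select_n(row, candidates, expected_density=0.0)
        counts = {n: run_al(row, ALConfig(n=n)).cluster_count for n in candidates}
        assert counts[best] == min(counts.values())

    def test_empty_candidates(self, clean_truth):
        with pytest.raises(ValueError):
            select_n(clean_truth.cloud, [], 1.0)
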