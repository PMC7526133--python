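import numpy as np
import pytest

from tillerscan import RowCloud, RowScenario, generate_row, make_fixture_suite


def build_handmade_row(
    cluster_centers=(0.15, 0.40, 0.65, 0.90),
    tillers_per_cluster=(3, 2, 5, 1),
    tiller_spacing=0.035,
    stem_top=0.25,
    leaf_lo=0.30,
    leaf_hi=0.42,
    leaf_span=(0.05, 1.00),
    stem_dz=0.002,
    rng=None,
):
    """Deterministic hand-built row: vertical stem columns plus a continuous
    leaf band above a point-free buffer, the structure the layering step
    assumes.  Returns (RowCloud, expected_total_tillers)."""
    pts = []
    for xc, k in zip(cluster_centers, tillers_per_cluster):
        for j in range(k):
            xb = xc + (j - (k - 1) / 2) * tiller_spacing
            z = np.arange(0.02, stem_top, stem_dz)
            pts.append(np.column_stack([np.full_like(z, xb), np.zeros_like(z), z]))
    xs = np.arange(leaf_span[0], leaf_span[1], 0.004)
    zs = np.arange(leaf_lo, leaf_hi, 0.004)
    gx, gz = np.meshgrid(xs, zs)
    pts.append(np.column_stack([gx.ravel(), np.zeros(gx.size), gz.ravel()]))
    cloud = RowCloud(np.vstack(pts))
    return cloud, int(sum(tillers_per_cluster))


@pytest.fixture
def handmade_row():
    return build_handmade_row()


@pytest.fixture(scope="session")
def clean_truth():
    """One default synthetic row (no noise, bridged gaps) with ground truth."""
    return generate_row(RowScenario(seed=1))


@pytest.fixture(scope="session")
def fixture_suite(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixtures")
    manifest = make_fixture_suite(out, base_seed=0)
    return out, manifest
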