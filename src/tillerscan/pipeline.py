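"""End-to-end tiller counting: AL segmentation -> HC counting -> plot density.

One preprocessed row per plot is counted (``T_row``), then scaled to the
plot-level tiller density ``T_plot = T_row * r / S`` where ``r`` is the
number of rows in the plot and ``S`` its area in square meters.  A
sensitivity sweep over the HC stop distance ``d`` reuses the AL result,
since ``d`` acts only in the clustering stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from . import __version__
from .io_preprocess import RowCloud
from .adaptive_layering import ALConfig, ALResult, run_al
from .hierarchical_clustering import (
    HCConfig,
    TillerCountPerCluster,
    count_tillers_in_cluster,
)

__all__ = ["PlotSpec", "TillerResult", "count_row", "to_plot_density", "sweep_d"]

log = logging.getLogger("tillerscan")


@dataclass
class PlotSpec:
    """Plot geometry used to convert a row count to a density.

    r
        Number of rows in the plot.
    S
        Plot area in square meters.
    row_spacing
        Optional row spacing in meters (informational only).
    """

    r: int
    S: float
    row_spacing: float | None = None

    def __post_init__(self) -> None:
        if self.r < 1:
            raise ValueError("r (rows per plot) must be >= 1")
        if self.S <= 0:
            raise ValueError("S (plot area) must be positive")


@dataclass
class TillerResult:
    """Per-row tiller counting result with full parameter provenance."""

    per_cluster: list[TillerCountPerCluster]
    T_row: int
    parameters: dict
    T_plot: float | None = None
    separation_layer: int | None = None

    def to_dict(self) -> dict:
        return {
            "T_row": self.T_row,
            "T_plot": self.T_plot,
            "separation_layer": self.separation_layer,
            "per_cluster": [
                {"cluster_id": c.cluster_id, "tiller_count": c.tiller_count}
                for c in self.per_cluster
            ],
            "parameters": self.parameters,
            "version": __version__,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)


def count_row(
    row: RowCloud,
    al_config: ALConfig | None = None,
    hc_config: HCConfig | None = None,
    al_result: ALResult | None = None,
) -> TillerResult:
    """Count the tillers of one row: AL cluster segmentation, then HC per cluster.

    ``T_row`` is the sum of per-cluster tiller counts.  A precomputed
    ``al_result`` may be supplied (the d-sweep does this); otherwise the AL
    step runs with ``al_config``.
    """
    al_cfg = al_config or ALConfig()
    hc_cfg = hc_config or HCConfig()
    al = al_result if al_result is not None else run_al(row, al_cfg)
    log.info(
        "AL: %d clusters, separation layer %d", al.cluster_count, al.separation_layer
    )
    log.debug("AL T per pair: %s", al.T_per_pair)

    per_cluster = []
    for seg in al.clusters:
        try:
            per_cluster.append(count_tillers_in_cluster(seg, hc_cfg))
        except ValueError as exc:
            raise ValueError(
                f"HC failed on cluster {seg.cluster_id} "
                f"(x interval {seg.x_interval}): {exc}"
            ) from exc
    T_row = int(sum(c.tiller_count for c in per_cluster))
    log.info("HC: T_row = %d over %d clusters", T_row, len(per_cluster))
    params = {"al": asdict(al.config), "hc": asdict(hc_cfg)}
    return TillerResult(
        per_cluster=per_cluster,
        T_row=T_row,
        parameters=params,
        separation_layer=al.separation_layer,
    )


def to_plot_density(T_row: int, plot: PlotSpec) -> float:
    """Plot-level tiller density: ``T_plot = T_row * r / S`` (tillers per m²)."""
    return T_row * plot.r / plot.S


def sweep_d(
    row: RowCloud,
    d_values,
    al_config: ALConfig | None = None,
    hc_config: HCConfig | None = None,
) -> pd.DataFrame:
    """Sensitivity of ``T_row`` to the HC stop distance ``d``.

    The AL segmentation is computed once and reused for every ``d``; only
    the clustering stage depends on the threshold.  Returns a DataFrame with
    columns ``d`` and ``T_row`` in the given order of ``d_values``; under
    single linkage ``T_row`` is non-increasing in ``d``.
    """
    d_values = list(d_values)
    if not d_values:
        raise ValueError("d_values must be non-empty")
    if any(d <= 0 for d in d_values):
        raise ValueError("all d values must be positive")
    al_cfg = al_config or ALConfig()
    hc_cfg = hc_config or HCConfig()
    al = run_al(row, al_cfg)
    rows = []
    for d in d_values:
        cfg = HCConfig(d_stop=d, linkage=hc_cfg.linkage, use_points=hc_cfg.use_points)
        result = count_row(row, al_cfg, cfg, al_result=al)
        rows.append({"d": d, "T_row": result.T_row})
    return pd.DataFrame(rows, columns=["d", "T_row"])
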