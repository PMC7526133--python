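"""Agreement metrics between estimated and reference tiller densities.

Implements the coefficient of determination (R²), the root mean square
error (RMSE) and the relative RMSE (RRMSE, in percent) for paired
observed/predicted densities.  Two published variants exist for R² and
RRMSE denominators; the conventional forms (reference mean) are the
defaults and the alternative typeset forms are available behind
``variant="as_printed"`` so both can be exercised and compared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PairedObservations",
    "EvalMetrics",
    "rmse",
    "r_squared",
    "rrmse",
    "evaluate_suite",
]


@dataclass
class PairedObservations:
    """Reference (O) and computed (P) tiller densities, tillers/m²."""

    O: np.ndarray
    P: np.ndarray

    def __post_init__(self) -> None:
        O = np.asarray(self.O, dtype=float).ravel()
        P = np.asarray(self.P, dtype=float).ravel()
        if O.shape != P.shape:
            raise ValueError(f"length mismatch: {O.size} reference vs {P.size} computed")
        if O.size == 0:
            raise ValueError("need at least one observation pair")
        if np.any(O < 0) or np.any(P < 0):
            raise ValueError("densities must be non-negative")
        self.O, self.P = O, P

    @property
    def n(self) -> int:
        return self.O.size


@dataclass
class EvalMetrics:
    """The three agreement metrics plus the formula variants used."""

    r_squared: float
    rmse: float
    rrmse: float  # percent
    r2_variant: str = "standard"
    rrmse_variant: str = "mean_obs"


def rmse(obs: PairedObservations) -> float:
    """Root mean square error between reference and computed densities."""
    return float(np.sqrt(np.mean((obs.O - obs.P) ** 2)))


def r_squared(obs: PairedObservations, variant: str = "standard") -> float:
    """Coefficient of determination.

    ``standard``: 1 - SS_res / SS_tot with the *reference* mean in the
    denominator (the universal convention).  ``as_printed``: the variant
    with the *computed* mean (P̄) in the denominator, as occasionally
    typeset in the applied literature.
    """
    if obs.n < 2:
        raise ValueError("R² needs at least 2 pairs")
    center = obs.O.mean() if variant == "standard" else obs.P.mean()
    if variant not in ("standard", "as_printed"):
        raise ValueError("variant must be 'standard' or 'as_printed'")
    denom = float(np.sum((obs.O - center) ** 2))
    if denom == 0:
        raise ValueError("zero-variance reference: R² undefined")
    return float(1.0 - np.sum((obs.O - obs.P) ** 2) / denom)


def rrmse(obs: PairedObservations, variant: str = "mean_obs") -> float:
    """Relative RMSE in percent.

    ``mean_obs``: RMSE divided by the mean reference density (conventional).
    ``as_printed``: RMSE divided by the mean *signed* difference O-P, a
    variant that appears in some typeset formulas.
    """
    if variant == "mean_obs":
        denom = float(obs.O.mean())
    elif variant == "as_printed":
        denom = float(np.mean(obs.O - obs.P))
    else:
        raise ValueError("variant must be 'mean_obs' or 'as_printed'")
    if denom == 0:
        raise ValueError(f"zero denominator for RRMSE variant {variant!r}")
    return float(rmse(obs) / denom * 100.0)


def evaluate_suite(
    results,
    r2_variant: str = "standard",
    rrmse_variant: str = "mean_obs",
) -> tuple[EvalMetrics, pd.DataFrame]:
    """Score a batch of (reference density, estimated density) pairs.

    Returns the three metrics plus a per-scenario table (observed,
    estimated, error) suitable for a report.  ``results`` may be a list of
    pairs or a mapping of scenario name to pair.
    """
    if isinstance(results, dict):
        names = list(results)
        pairs = [results[k] for k in names]
    else:
        pairs = list(results)
        names = [str(i) for i in range(len(pairs))]
    if len(pairs) < 2:
        raise ValueError("need at least 2 scenarios to evaluate")
    O = np.array([p[0] for p in pairs], dtype=float)
    P = np.array([p[1] for p in pairs], dtype=float)
    obs = PairedObservations(O, P)
    metrics = EvalMetrics(
        r_squared=r_squared(obs, r2_variant),
        rmse=rmse(obs),
        rrmse=rrmse(obs, rrmse_variant),
        r2_variant=r2_variant,
        rrmse_variant=rrmse_variant,
    )
    table = pd.DataFrame(
        {
            "scenario": names,
            "observed": O,
            "estimated": P,
            "error": P - O,
        }
    )
    return metrics, table
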