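"""Comparison-curve fit index (CCFI) and CCFI profiles.

For each curve procedure the empirical averaged curve is compared against
the mean curves of the taxonic and dimensional comparison ensembles via
the root-mean-square residual (RMSR).  The CCFI,

    CCFI = fit_dim / (fit_dim + fit_tax),

runs from 0 (dimensional) to 1 (taxonic); values in the open interval
(0.40, 0.60) are conventionally ambiguous.  The overall verdict uses the
mean CCFI across methods.  Because the assumed taxon base rate is itself
an assumption, a CCFI profile recomputes the index across a grid of base
rates (0.025 … 0.975 in steps of 0.025) with per-method aggregates and an
overall mean.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .comparison import (
    ComparisonEnsemble,
    generate_dimensional_comparison,
    generate_taxonic_comparison,
)
from .matrix import IndicatorMatrix
from .methods import Curve, CurveSet, MethodSettings, compute_curves
from .validity import round_half_up

__all__ = [
    "CCFIResult",
    "CCFISummary",
    "CCFIProfile",
    "curve_rmsr",
    "compute_ccfi",
    "ccfi_from_ensembles",
    "summarize_ccfi",
    "default_profile_grid",
    "ccfi_profile",
    "interpret_ccfi",
]

logger = logging.getLogger(__name__)

AMBIGUOUS_LOW = 0.40
AMBIGUOUS_HIGH = 0.60


@dataclass
class CCFIResult:
    """Fit of one method's empirical curve to both comparison structures."""

    method: str
    fit_tax: float
    fit_dim: float
    ccfi: float


@dataclass
class CCFISummary:
    """Per-method CCFIs, their mean, and the categorical interpretation."""

    results: dict[str, CCFIResult]
    mean_ccfi: float = field(init=False)
    interpretation: str = field(init=False)

    def __post_init__(self) -> None:
        if not self.results:
            raise ValueError("need at least one method result")
        self.mean_ccfi = float(
            np.mean([r.ccfi for r in self.results.values()])
        )
        self.interpretation = interpret_ccfi(self.mean_ccfi)

    def to_dict(self) -> dict:
        return {
            "per_method": {
                m: {"fit_tax": r.fit_tax, "fit_dim": r.fit_dim,
                    "ccfi": round(r.ccfi, 2)}
                for m, r in self.results.items()
            },
            "mean_ccfi": round(self.mean_ccfi, 2),
            "interpretation": self.interpretation,
        }


@dataclass
class CCFIProfile:
    """CCFI across assumed taxon base rates, with aggregates.

    ``table`` has one row per feasible base rate with per-method CCFIs and
    their cross-method mean (``ccfi_aggregate``); ``per_method_aggregate``
    is each method's mean over the grid, and ``overall_mean`` the mean of
    those per-method aggregates.  Aggregation uses full precision;
    rounding to 2 decimals happens only in reports.
    """

    table: pd.DataFrame
    per_method_aggregate: dict[str, float] = field(init=False)
    overall_mean: float = field(init=False)
    skipped_rates: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        methods = [c.removeprefix("ccfi_") for c in self.table.columns
                   if c.startswith("ccfi_") and c != "ccfi_aggregate"]
        if self.table.empty:
            raise ValueError("no feasible grid point in the profile")
        self.per_method_aggregate = {
            m: float(self.table[f"ccfi_{m}"].mean()) for m in methods
        }
        self.overall_mean = float(
            np.mean(list(self.per_method_aggregate.values()))
        )

    def to_dict(self) -> dict:
        return {
            "per_method_aggregate": {
                m: round(v, 2) for m, v in self.per_method_aggregate.items()
            },
            "overall_mean": round(self.overall_mean, 2),
            "skipped_rates": self.skipped_rates,
        }


def interpret_ccfi(value: float) -> str:
    """Band rule: < 0.40 dimensional, > 0.60 taxonic, else ambiguous."""
    if value < AMBIGUOUS_LOW:
        return "dimensional"
    if value > AMBIGUOUS_HIGH:
        return "taxonic"
    return "ambiguous"


def curve_rmsr(empirical: Curve, simulated_mean: Curve) -> float:
    """Root-mean-square residual between two curves of equal length."""
    if len(empirical) != len(simulated_mean):
        raise ValueError(
            f"curve length mismatch: {len(empirical)} vs {len(simulated_mean)}"
        )
    return float(np.sqrt(np.mean((empirical.y - simulated_mean.y) ** 2)))


def compute_ccfi(fit_dim: float, fit_tax: float) -> float:
    """CCFI = fit_dim / (fit_dim + fit_tax); 0.5 when both fits are 0."""
    if fit_dim < 0 or fit_tax < 0:
        raise ValueError("fits must be non-negative")
    denom = fit_dim + fit_tax
    if denom == 0:
        warnings.warn("both fits are zero; CCFI degenerate, reporting 0.5")
        return 0.5
    return float(fit_dim / denom)


def ccfi_from_ensembles(
    empirical: dict[str, CurveSet],
    taxonic: ComparisonEnsemble,
    dimensional: ComparisonEnsemble,
    per_set_fit: bool = False,
) -> dict[str, CCFIResult]:
    """Per-method CCFI from the empirical curves and both ensembles.

    By default fit is the RMSR between the empirical averaged curve and
    the ensemble's mean curve; ``per_set_fit`` switches to the mean of
    per-dataset RMSRs instead.
    """
    out: dict[str, CCFIResult] = {}
    for method, curveset in empirical.items():
        emp = curveset.averaged_curve
        if per_set_fit:
            fit_tax = float(np.mean(
                [curve_rmsr(emp, c) for c in taxonic.curves[method]]
            ))
            fit_dim = float(np.mean(
                [curve_rmsr(emp, c) for c in dimensional.curves[method]]
            ))
        else:
            fit_tax = curve_rmsr(emp, taxonic.mean_curve[method])
            fit_dim = curve_rmsr(emp, dimensional.mean_curve[method])
        out[method] = CCFIResult(
            method=method, fit_tax=fit_tax, fit_dim=fit_dim,
            ccfi=compute_ccfi(fit_dim, fit_tax),
        )
    return out


def summarize_ccfi(results: dict[str, CCFIResult] | list[CCFIResult]
                   ) -> CCFISummary:
    """Mean CCFI over methods plus the band interpretation."""
    if isinstance(results, list):
        results = {r.method: r for r in results}
    return CCFISummary(results=dict(results))


def default_profile_grid() -> np.ndarray:
    """Assumed base rates 0.025 … 0.975 in steps of 0.025 (39 values)."""
    return np.round(np.arange(1, 40) * 0.025, 3)


def ccfi_profile(
    matrix: IndicatorMatrix,
    rng: np.random.Generator,
    grid: np.ndarray | None = None,
    settings: MethodSettings | None = None,
    n_sets: int = 100,
    max_iter: int = 100,
    empirical: dict[str, CurveSet] | None = None,
    dimensional: ComparisonEnsemble | None = None,
    lmode_grid: np.ndarray | None = None,
    per_set_fit: bool = False,
) -> CCFIProfile:
    """CCFI at every feasible assumed base rate on the grid.

    The dimensional ensemble does not depend on the base rate and is
    computed once (or supplied); the taxonic ensemble is regenerated per
    rate.  Rates whose putative groups are too small to estimate
    within-group correlations (< k+2 cases) are skipped with a warning.
    """
    settings = settings or MethodSettings()
    if grid is None:
        grid = default_profile_grid()
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0) or grid.min() <= 0 or grid.max() >= 1:
        raise ValueError("grid must be strictly increasing within (0, 1)")

    if empirical is None:
        empirical = compute_curves(matrix, settings, rng, lmode_grid)
    if lmode_grid is None and "lmode" in empirical:
        lmode_grid = empirical["lmode"].averaged_curve.x
    if dimensional is None:
        dimensional = generate_dimensional_comparison(
            matrix, n_sets, rng, settings, lmode_grid, max_iter
        )

    n, k = matrix.n, matrix.k
    rows = []
    skipped: list[float] = []
    for rate in grid:
        t = round_half_up(n * rate)
        if min(t, n - t) < k + 2:
            skipped.append(float(rate))
            continue
        taxonic = generate_taxonic_comparison(
            matrix, float(rate), n_sets, rng, settings, lmode_grid, max_iter
        )
        results = ccfi_from_ensembles(empirical, taxonic, dimensional,
                                      per_set_fit)
        row = {"base_rate": float(rate)}
        for m, r in results.items():
            row[f"ccfi_{m}"] = r.ccfi
        row["ccfi_aggregate"] = float(
            np.mean([r.ccfi for r in results.values()])
        )
        rows.append(row)
    if skipped:
        warnings.warn(
            f"skipped {len(skipped)} infeasible base rate(s): {skipped}"
        )
    if not rows:
        raise ValueError("no feasible base rate on the profile grid")
    return CCFIProfile(table=pd.DataFrame(rows), skipped_rates=skipped)
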