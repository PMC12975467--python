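"""End-to-end analysis pipeline and sensitivity harness.

Stages, in order: load → optional screening filter → optional subscale
scoring → optional log10 transform → descriptives + validity gate →
dimensional and taxonic comparison ensembles at the assumed base rate →
curve procedures on empirical and simulated data → per-method CCFI →
mean CCFI and interpretation → optional CCFI profile → report files.

A single master seed spawns per-stage child streams, so identical config
plus seed reproduces identical outputs, and toggling the profile stage
does not change the fixed-base-rate results.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from ._rng import stage_rng
from .ccfi import (
    CCFIProfile,
    CCFISummary,
    ccfi_from_ensembles,
    ccfi_profile,
    default_profile_grid,
    summarize_ccfi,
)
from .comparison import (
    ComparisonEnsemble,
    generate_dimensional_comparison,
    generate_taxonic_comparison,
)
from .matrix import FilterRule, IndicatorMatrix, ScoringMap
from .methods import (
    CurveSet,
    MethodSettings,
    compute_curves,
    estimate_base_rates,
)
from .validity import (
    ValidityReport,
    build_validity_report,
    filter_valid_indicators,
)

__all__ = ["RunConfig", "AnalysisResult", "run_full_analysis",
           "run_sensitivity"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one full analysis run."""

    input: str | None = None
    indicators: list[str] | None = None
    delimiter: str = ","
    missing_policy: str = "fail"
    screening_columns: list[str] | None = None
    scoring: dict[str, list[str]] | None = None
    log10: bool = False
    base_rate: float = 0.25
    d_threshold: float = 1.25
    methods: tuple[str, ...] = ("mambac", "maxeig", "lmode")
    n_sets: int = 100
    max_iter: int = 100
    per_set_fit: bool = False
    profile: bool = False
    profile_grid: list[float] | None = None
    profile_n_sets: int | None = None
    n_cuts: int = 50
    end_offset: int = 25
    replications: int = 10
    n_windows: int = 50
    overlap: float = 0.9
    grid_points: int = 512
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.base_rate < 1:
            raise ValueError("base_rate must lie in (0, 1)")
        self.methods = tuple(self.methods)
        if not self.methods:
            raise ValueError("at least one method required")

    def settings(self) -> MethodSettings:
        return MethodSettings(
            methods=self.methods,
            n_cuts=self.n_cuts,
            end_offset=self.end_offset,
            replications=self.replications,
            n_windows=self.n_windows,
            overlap=self.overlap,
            grid_points=self.grid_points,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["methods"] = list(self.methods)
        return d

    @classmethod
    def from_json(cls, path: str | Path, **overrides) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass
class AnalysisResult:
    """Everything one pipeline run produced."""

    config: RunConfig
    matrix: IndicatorMatrix
    validity: ValidityReport
    empirical_curves: dict[str, CurveSet]
    taxonic: ComparisonEnsemble
    dimensional: ComparisonEnsemble
    ccfi_summary: CCFISummary
    base_rates: dict
    profile: CCFIProfile | None = None
    n_screened_out: int = 0
    report: dict = field(default_factory=dict)
    written_files: list[Path] = field(default_factory=list)


def _prepare_matrix(config: RunConfig,
                    matrix: IndicatorMatrix | None) -> tuple[IndicatorMatrix, int]:
    removed = 0
    if matrix is None:
        if config.input is None:
            raise ValueError("config.input or an in-memory matrix is required")
        table = tio.load_table(config.input, delimiter=config.delimiter)
    else:
        table = matrix.to_frame()
    if config.screening_columns:
        table, removed = tio.apply_screening_filter(
            table, FilterRule(screening_columns=config.screening_columns)
        )
    if config.scoring:
        out = tio.score_subscales(table, ScoringMap(config.scoring))
    else:
        columns = config.indicators or [str(c) for c in table.columns]
        missing = [c for c in columns if c not in table.columns]
        if missing:
            raise KeyError(f"indicator columns not found: {missing}")
        sub = table[columns].apply(pd.to_numeric, errors="coerce")
        if sub.isna().to_numpy().any():
            if config.missing_policy == "fail":
                raise ValueError("missing or non-numeric values in indicators")
            sub = sub.dropna()
        out = IndicatorMatrix(sub.to_numpy(dtype=float), columns,
                              list(sub.index))
    if config.log10:
        out = tio.log10_transform(out)
    return out, removed


def run_full_analysis(
    config: RunConfig, matrix: IndicatorMatrix | None = None
) -> AnalysisResult:
    """Execute the full taxometric analysis described by ``config``.

    ``matrix`` may be passed directly to skip file loading (the synthetic
    generator and tests use this path).
    """
    t0 = time.perf_counter()
    prepared, removed = _prepare_matrix(config, matrix)
    logger.info("prepared matrix: n=%d, k=%d (screened out %d)",
                prepared.n, prepared.k, removed)

    validity = build_validity_report(
        prepared, base_rate=config.base_rate, threshold=config.d_threshold
    )
    valid_names = filter_valid_indicators(
        validity.table["d"].to_numpy(),
        list(validity.table["indicator"]),
        threshold=config.d_threshold,
    )
    analysis_matrix = prepared.select(valid_names)
    logger.info("validity gate: %d/%d indicators retained",
                len(valid_names), prepared.k)

    settings = config.settings()
    empirical = compute_curves(
        analysis_matrix, settings, stage_rng(config.seed, "methods")
    )
    lmode_grid = (empirical["lmode"].averaged_curve.x
                  if "lmode" in empirical else None)

    dimensional = generate_dimensional_comparison(
        analysis_matrix, config.n_sets,
        stage_rng(config.seed, "comparison_dim"),
        settings, lmode_grid, config.max_iter,
    )
    taxonic = generate_taxonic_comparison(
        analysis_matrix, config.base_rate, config.n_sets,
        stage_rng(config.seed, "comparison_tax"),
        settings, lmode_grid, config.max_iter,
    )
    results = ccfi_from_ensembles(empirical, taxonic, dimensional,
                                  config.per_set_fit)
    summary = summarize_ccfi(results)
    base_rates = estimate_base_rates(empirical)

    profile = None
    if config.profile:
        grid = (np.asarray(config.profile_grid, dtype=float)
                if config.profile_grid else default_profile_grid())
        profile_rng = stage_rng(config.seed, "profile")
        n_sets = config.profile_n_sets or config.n_sets
        reuse_dim = dimensional if n_sets == config.n_sets else None
        profile = ccfi_profile(
            analysis_matrix, profile_rng, grid, settings, n_sets,
            config.max_iter, empirical=empirical, dimensional=reuse_dim,
            lmode_grid=lmode_grid, per_set_fit=config.per_set_fit,
        )

    report = {
        "config": config.to_dict(),
        "seed": config.seed,
        "n_cases": prepared.n,
        "n_screened_out": removed,
        "validity": validity.to_dict(),
        "ccfi": summary.to_dict(),
        "base_rates": {
            "per_method": {
                m: (round(v, 2) if v is not None else None)
                for m, v in base_rates["per_method"].items()
            },
            "mean": round(base_rates["mean"], 2),
        },
        "profile": profile.to_dict() if profile is not None else None,
        "interpretation": summary.interpretation,
    }
    logger.info("analysis finished in %.2f s", time.perf_counter() - t0)

    result = AnalysisResult(
        config=config, matrix=analysis_matrix, validity=validity,
        empirical_curves=empirical, taxonic=taxonic, dimensional=dimensional,
        ccfi_summary=summary, base_rates=base_rates, profile=profile,
        n_screened_out=removed, report=report,
    )
    if config.out_dir:
        result.written_files = tio.write_report(
            config.out_dir, report,
            validity_table=validity.table,
            curve_tables=build_curve_tables(result),
            profile_table=profile.table if profile is not None else None,
        )
    return result


def build_curve_tables(result: AnalysisResult) -> dict[str, pd.DataFrame]:
    """Per-method curve table: empirical curve plus both ensemble bands."""
    tables = {}
    for method, curveset in result.empirical_curves.items():
        emp = curveset.averaged_curve
        tax_lo, tax_hi = result.taxonic.envelope[method]
        dim_lo, dim_hi = result.dimensional.envelope[method]
        tables[method] = pd.DataFrame({
            "point_index": np.arange(len(emp)),
            "x": emp.x,
            "y_empirical": emp.y,
            "y_tax_mean": result.taxonic.mean_curve[method].y,
            "y_tax_lo": tax_lo,
            "y_tax_hi": tax_hi,
            "y_dim_mean": result.dimensional.mean_curve[method].y,
            "y_dim_lo": dim_lo,
            "y_dim_hi": dim_hi,
        })
    return tables


def run_sensitivity(
    config: RunConfig,
    variants: list[dict],
    matrix: IndicatorMatrix | None = None,
) -> pd.DataFrame:
    """Re-run the pipeline under each config delta with a shared seed.

    Each variant is a dict of RunConfig field overrides (plus an optional
    ``"label"``).  Per-variant failures are recorded in the table; the
    remaining variants still run.
    """
    if not variants:
        raise ValueError("variant list must not be empty")
    rows = []
    for i, delta in enumerate(variants):
        delta = dict(delta)
        label = delta.pop("label", f"variant_{i}")
        row: dict = {"variant": label}
        try:
            vconfig = dataclasses.replace(config, out_dir=None, **delta)
            res = run_full_analysis(vconfig, matrix=matrix)
            for m, r in res.ccfi_summary.results.items():
                row[f"ccfi_{m}"] = r.ccfi
            row["mean_ccfi"] = res.ccfi_summary.mean_ccfi
            row["interpretation"] = res.ccfi_summary.interpretation
            row["n_cases"] = res.matrix.n
            row["error"] = None
        except Exception as exc:  # noqa: BLE001 - reported per variant
            logger.warning("variant %s failed: %s", label, exc)
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)
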