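"""Reading indicator data and writing analysis reports.

Input is delimited text (CSV with a header row, period decimal separator).
Output is a small file set: ``report.json`` with all scalar results,
``validity.csv`` mirroring the indicator-quality table, one
``curves_<method>.csv`` per curve procedure, and ``profile.csv`` when a
CCFI profile was run.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix import FilterRule, IndicatorMatrix, ScoringMap

__all__ = [
    "load_indicator_matrix",
    "load_table",
    "apply_screening_filter",
    "score_subscales",
    "log10_transform",
    "write_report",
]

logger = logging.getLogger(__name__)


def load_table(path: str | Path, delimiter: str = ",") -> pd.DataFrame:
    """Read a delimited text file with a header row into a DataFrame."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    return pd.read_csv(path, sep=delimiter)


def load_indicator_matrix(
    path: str | Path,
    columns: Sequence[str],
    missing_policy: str = "fail",
    delimiter: str = ",",
) -> IndicatorMatrix:
    """Load selected indicator columns from a delimited text file.

    Parameters
    ----------
    columns
        Column labels to keep, in the requested order.
    missing_policy
        ``"fail"`` raises on any missing or non-numeric cell in the
        requested columns; ``"drop_case"`` removes cases with any missing
        value in those columns (the number dropped is logged).
    """
    if missing_policy not in ("fail", "drop_case"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    table = load_table(path, delimiter=delimiter)
    missing_cols = [c for c in columns if c not in table.columns]
    if missing_cols:
        raise KeyError(f"columns not in {path}: {missing_cols}")
    sub = table[list(columns)].apply(pd.to_numeric, errors="coerce")
    bad = sub.isna()
    if bad.to_numpy().any():
        if missing_policy == "fail":
            row = int(bad.any(axis=1).idxmax())
            col = bad.loc[row].idxmax()
            raise ValueError(
                f"missing or non-numeric value at row {row}, column {col!r} "
                "(missing_policy='fail')"
            )
        keep = ~bad.any(axis=1)
        dropped = int((~keep).sum())
        logger.info("dropped %d case(s) with missing values", dropped)
        sub = sub.loc[keep]
        if len(sub) == 0:
            raise ValueError("no cases remain after dropping missing values")
    return IndicatorMatrix(
        sub.to_numpy(dtype=float), list(columns), list(sub.index)
    )


def apply_screening_filter(
    table: pd.DataFrame, rule: FilterRule
) -> tuple[pd.DataFrame, int]:
    """Drop cases scoring 0 on *every* screening column.

    Retained rows are unmodified and keep their original order.  Returns
    the filtered table and the number of removed cases.
    """
    missing = [c for c in rule.screening_columns if c not in table.columns]
    if missing:
        raise KeyError(f"screening columns not in table: {missing}")
    screen = table[rule.screening_columns].to_numpy(dtype=float)
    drop = np.all(screen == 0, axis=1)
    removed = int(drop.sum())
    if removed:
        logger.info(
            "screening filter removed %d case(s) scoring 0 on all of %s",
            removed, rule.screening_columns,
        )
    return table.loc[~drop], removed


def score_subscales(table: pd.DataFrame, scoring: ScoringMap) -> IndicatorMatrix:
    """Sum item columns into factor scores (one indicator per factor)."""
    scoring.validate_against(table.columns)
    cols = {}
    for factor, items in scoring.factors.items():
        cols[factor] = table[list(items)].to_numpy(dtype=float).sum(axis=1)
    values = np.column_stack([cols[f] for f in scoring.factors])
    return IndicatorMatrix(values, list(scoring.factors), list(table.index))


def log10_transform(matrix: IndicatorMatrix) -> IndicatorMatrix:
    """Apply x → log10(x + 1) to every entry.

    The +1 offset makes the transform zero-safe for bounded item scores
    (log10(0 + 1) = 0) while remaining strictly monotone.  Negative inputs
    are rejected.
    """
    if np.any(matrix.values < 0):
        raise ValueError("log10 transform requires non-negative values")
    return IndicatorMatrix(
        np.log10(matrix.values + 1.0),
        list(matrix.indicator_names),
        list(matrix.case_ids),
    )


def _round_floats(obj, ndigits=10):
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if not np.isfinite(v) else round(v, ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist(), ndigits)
    return obj


def write_report(
    out_dir: str | Path,
    report: Mapping,
    validity_table: pd.DataFrame | None = None,
    curve_tables: Mapping[str, pd.DataFrame] | None = None,
    profile_table: pd.DataFrame | None = None,
) -> list[Path]:
    """Write report.json plus the CSV artifacts; returns written paths.

    All numeric content is deterministic for a given configuration and
    seed, so re-running reproduces byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    path = out / "report.json"
    path.write_text(json.dumps(_round_floats(dict(report)), indent=2) + "\n")
    written.append(path)

    if validity_table is not None:
        path = out / "validity.csv"
        validity_table.to_csv(path, index=False, float_format="%.10g")
        written.append(path)
    for method, table in (curve_tables or {}).items():
        path = out / f"curves_{method}.csv"
        table.to_csv(path, index=False, float_format="%.10g")
        written.append(path)
    if profile_table is not None:
        path = out / "profile.csv"
        profile_table.to_csv(path, index=False, float_format="%.10g")
        written.append(path)
    return written
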