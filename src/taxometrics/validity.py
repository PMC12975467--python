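"""Descriptive screening and the indicator-validity gate.

Taxometric procedures require indicators that separate the putative taxon
from its complement.  The conventional gate is Cohen's d >= 1.25 between
the extremes of the sample, with putative groups formed by ranking cases
on their standardized indicator total and cutting at the assumed taxon
base rate.  At least three indicators must survive the gate for the curve
procedures to run.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import IndicatorMatrix

__all__ = [
    "Membership",
    "ValidityReport",
    "ValidityError",
    "descriptives",
    "classify_putative_groups",
    "cohens_d",
    "filter_valid_indicators",
    "build_validity_report",
]

logger = logging.getLogger(__name__)

#: conventional minimum Cohen's d for a valid taxometric indicator
DEFAULT_D_THRESHOLD = 1.25


class ValidityError(RuntimeError):
    """Raised when fewer than three indicators pass the validity gate."""


@dataclass
class Membership:
    """Putative taxon assignment: 1 = taxon, 0 = complement."""

    flags: np.ndarray
    taxon_count: int

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=int)
        n1 = int(self.flags.sum())
        if n1 != self.taxon_count:
            raise ValueError("taxon_count does not match flags")
        if not (0 < self.taxon_count < self.flags.size):
            raise ValueError("both groups must be non-empty")

    @property
    def n(self) -> int:
        return self.flags.size

    @property
    def taxon_index(self) -> np.ndarray:
        return np.flatnonzero(self.flags == 1)

    @property
    def complement_index(self) -> np.ndarray:
        return np.flatnonzero(self.flags == 0)


@dataclass
class ValidityReport:
    """Per-indicator descriptives, Cohen's d and the valid/invalid flag."""

    table: pd.DataFrame  # columns: indicator, mean, sd, skewness, kurtosis, d, valid
    threshold: float = DEFAULT_D_THRESHOLD

    @property
    def valid_indicators(self) -> list[str]:
        return list(self.table.loc[self.table["valid"], "indicator"])

    @property
    def invalid_indicators(self) -> list[str]:
        return list(self.table.loc[~self.table["valid"], "indicator"])

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "indicators": self.table.to_dict(orient="records"),
        }


def round_half_up(x: float) -> int:
    """round(n*P) with ties away from zero (avoids banker's rounding)."""
    return int(np.floor(x + 0.5))


def descriptives(matrix: IndicatorMatrix) -> pd.DataFrame:
    """Mean, SD (n-1 denominator), skewness and excess kurtosis per indicator.

    Skewness is the standardized third moment g1 and kurtosis the excess
    standardized fourth moment g2 (normal → 0).  Constant indicators get
    NaN skewness/kurtosis rather than a silent zero.
    """
    if matrix.n < 3:
        raise ValueError("descriptives require at least 3 cases")
    x = matrix.values
    sd = x.std(axis=0, ddof=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        skew = stats.skew(x, axis=0, bias=True)
        kurt = stats.kurtosis(x, axis=0, fisher=True, bias=True)
    constant = sd == 0
    skew = np.where(constant, np.nan, skew)
    kurt = np.where(constant, np.nan, kurt)
    return pd.DataFrame(
        {
            "indicator": matrix.indicator_names,
            "mean": x.mean(axis=0),
            "sd": sd,
            "skewness": skew,
            "kurtosis": kurt,
        }
    )


def classify_putative_groups(
    matrix: IndicatorMatrix, base_rate: float
) -> Membership:
    """Split the sample into putative taxon and complement.

    Each indicator is standardized, the per-case total formed, and the
    ``round(n * base_rate)`` cases with the highest totals flagged as the
    putative taxon.  Ties at the boundary are broken by stable original
    case order (reproducible; a warning is logged when it happens).
    """
    if not 0 < base_rate < 1:
        raise ValueError("base_rate must lie in (0, 1)")
    n = matrix.n
    t = round_half_up(n * base_rate)
    if not 1 <= t <= n - 1:
        raise ValueError(
            f"base_rate {base_rate} yields taxon size {t} outside [1, {n - 1}]"
        )
    x = matrix.values
    sd = x.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)  # constant column contributes 0 to ranking
    totals = ((x - x.mean(axis=0)) / sd).sum(axis=1)
    order = np.argsort(-totals, kind="stable")
    if t < n and totals[order[t - 1]] == totals[order[t]]:
        logger.warning(
            "ties at the putative-taxon boundary broken by stable case order"
        )
    flags = np.zeros(n, dtype=int)
    flags[order[:t]] = 1
    return Membership(flags=flags, taxon_count=t)


def cohens_d(matrix: IndicatorMatrix, groups: Membership) -> np.ndarray:
    """Per-indicator Cohen's d between taxon and complement.

    d = (mean_taxon − mean_complement) / pooled SD, with the usual pooled
    variance ((n1−1)s1² + (n2−1)s2²)/(n1+n2−2).  The sign is preserved;
    a zero pooled SD yields NaN.
    """
    if groups.n != matrix.n:
        raise ValueError("membership length does not match matrix")
    g1 = matrix.values[groups.taxon_index]
    g2 = matrix.values[groups.complement_index]
    n1, n2 = len(g1), len(g2)
    if min(n1, n2) < 2:
        raise ValueError("both groups need at least 2 cases")
    s1 = g1.var(axis=0, ddof=1)
    s2 = g2.var(axis=0, ddof=1)
    pooled = np.sqrt(((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (g1.mean(axis=0) - g2.mean(axis=0)) / pooled
    return np.where(pooled == 0, np.nan, d)


def filter_valid_indicators(
    d_values: np.ndarray,
    names: list[str],
    threshold: float = DEFAULT_D_THRESHOLD,
) -> list[str]:
    """Return indicators with d >= threshold (inclusive), preserving order.

    Raises :class:`ValidityError` naming the offenders when fewer than
    three indicators survive — the curve procedures need at least three.
    """
    d_values = np.asarray(d_values, dtype=float)
    if len(d_values) != len(names):
        raise ValueError("d_values and names lengths differ")
    valid = [n for n, d in zip(names, d_values) if np.isfinite(d) and d >= threshold]
    if len(valid) < 3:
        offenders = [
            f"{n} (d={d:.2f})"
            for n, d in zip(names, d_values)
            if not (np.isfinite(d) and d >= threshold)
        ]
        raise ValidityError(
            f"only {len(valid)} indicator(s) reach d >= {threshold}; "
            f"at least 3 required. Failing: {', '.join(offenders)}"
        )
    return valid


def build_validity_report(
    matrix: IndicatorMatrix,
    base_rate: float = 0.25,
    threshold: float = DEFAULT_D_THRESHOLD,
) -> ValidityReport:
    """Descriptives + Cohen's d + valid flag for every candidate indicator."""
    desc = descriptives(matrix)
    groups = classify_putative_groups(matrix, base_rate)
    d = cohens_d(matrix, groups)
    desc["d"] = d
    desc["valid"] = np.isfinite(d) & (d >= threshold)
    return ValidityReport(table=desc, threshold=threshold)
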