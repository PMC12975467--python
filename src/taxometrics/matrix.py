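"""Core data containers for taxometric analysis.

The central object is :class:`IndicatorMatrix`, an n-cases × k-indicators
numeric score matrix with column labels and case identifiers.  Indicators
are questionnaire scores (item scores or subscale sums); downstream stages
(validity screening, curve procedures, comparison-data generation) all
consume this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["IndicatorMatrix", "ScoringMap", "FilterRule"]


@dataclass
class IndicatorMatrix:
    """An n × k matrix of indicator scores.

    Parameters
    ----------
    values
        Real-valued array of shape ``(n, k)``; every entry must be finite
        (missing data are handled at load time, never stored here).
    indicator_names
        ``k`` unique column labels.
    case_ids
        ``n`` case identifiers (row order is meaningful and preserved by
        every operation in the package).
    """

    values: np.ndarray
    indicator_names: list[str]
    case_ids: list = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n, k = self.values.shape
        if k < 1:
            raise ValueError("need at least one indicator")
        if n < 2:
            raise ValueError("need at least two cases")
        self.indicator_names = [str(c) for c in self.indicator_names]
        if len(self.indicator_names) != k:
            raise ValueError(
                f"{len(self.indicator_names)} names for {k} columns"
            )
        if len(set(self.indicator_names)) != k:
            raise ValueError("indicator names must be unique")
        if self.case_ids is None:
            self.case_ids = list(range(n))
        else:
            self.case_ids = list(self.case_ids)
        if len(self.case_ids) != n:
            raise ValueError(f"{len(self.case_ids)} case ids for {n} rows")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("all values must be finite (no NaN/inf)")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.indicator_names.index(name)
        except ValueError:
            raise KeyError(f"unknown indicator {name!r}") from None
        return self.values[:, j]

    def select(self, names: Sequence[str]) -> "IndicatorMatrix":
        """Restrict to the given indicators, in the given order."""
        idx = []
        for name in names:
            if name not in self.indicator_names:
                raise KeyError(f"unknown indicator {name!r}")
            idx.append(self.indicator_names.index(name))
        return IndicatorMatrix(
            self.values[:, idx], [self.indicator_names[j] for j in idx],
            list(self.case_ids),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, columns=self.indicator_names, index=self.case_ids
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "IndicatorMatrix":
        return cls(
            frame.to_numpy(dtype=float),
            [str(c) for c in frame.columns],
            list(frame.index),
        )


@dataclass
class ScoringMap:
    """Factor → ordered item columns, for sum scoring of subscales.

    Each factor score is the row-wise sum of its item columns.  An item may
    belong to at most one factor.
    """

    factors: Mapping[str, Sequence[str]]

    def __post_init__(self) -> None:
        self.factors = {str(f): [str(c) for c in cols]
                        for f, cols in dict(self.factors).items()}
        if not self.factors:
            raise ValueError("scoring map must define at least one factor")
        seen: set[str] = set()
        for factor, cols in self.factors.items():
            if not cols:
                raise ValueError(f"factor {factor!r} has no items")
            overlap = seen & set(cols)
            if overlap:
                raise ValueError(
                    f"items {sorted(overlap)} appear in more than one factor"
                )
            seen |= set(cols)

    def validate_against(self, columns: Sequence[str]) -> None:
        available = set(map(str, columns))
        for factor, cols in self.factors.items():
            missing = [c for c in cols if c not in available]
            if missing:
                raise KeyError(
                    f"factor {factor!r} references missing columns {missing}"
                )


@dataclass
class FilterRule:
    """Case-exclusion rule on screening columns.

    The only predicate currently supported is ``all_zero``: drop a case
    when *every* screening column equals 0 (the skip-structure floor-effect
    exclusion used with screening items of ideation questionnaires).
    """

    screening_columns: list[str]
    drop_if: str = "all_zero"

    def __post_init__(self) -> None:
        self.screening_columns = [str(c) for c in self.screening_columns]
        if not self.screening_columns:
            raise ValueError("need at least one screening column")
        if self.drop_if != "all_zero":
            raise ValueError(f"unknown predicate {self.drop_if!r}")
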