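"""Structure-matched simulated comparison data.

The comparison-data technique judges an empirical taxometric curve against
curves from simulated datasets that reproduce the empirical marginal
distributions and correlation structure under each candidate latent
structure — one population generated from a single continuous structure
(dimensional) and one from a two-group mixture at the assumed taxon base
rate (taxonic).  Datasets are produced by an iterative rank-reordering
algorithm: latent multivariate-normal draws are repeatedly re-correlated
until, after each column's values are replaced by the rank-ordered
bootstrap marginal, the achieved correlation matrix matches the target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .matrix import IndicatorMatrix
from .methods import Curve, CurveSet, MethodSettings, compute_curves
from .validity import classify_putative_groups

__all__ = [
    "ComparisonEnsemble",
    "gen_data_matched",
    "generate_dimensional_comparison",
    "generate_taxonic_comparison",
]

logger = logging.getLogger(__name__)


@dataclass
class ComparisonEnsemble:
    """Curves from one population of simulated comparison datasets."""

    structure: str  # "taxonic" | "dimensional"
    n_sets: int
    curves: dict[str, list[Curve]]  # per-method, one averaged curve per set
    mean_curve: dict[str, Curve] = field(init=False)
    envelope: dict[str, tuple[np.ndarray, np.ndarray]] = field(init=False)
    base_rate: float | None = None

    def __post_init__(self) -> None:
        if self.structure not in ("taxonic", "dimensional"):
            raise ValueError(f"unknown structure {self.structure!r}")
        self.mean_curve = {}
        self.envelope = {}
        for method, curves in self.curves.items():
            lengths = {len(c) for c in curves}
            if len(lengths) != 1:
                raise ValueError(f"{method}: curves differ in length")
            ys = np.array([c.y for c in curves])
            self.mean_curve[method] = Curve(curves[0].x, ys.mean(axis=0))
            self.envelope[method] = (ys.min(axis=0), ys.max(axis=0))


def _rmsr_offdiag(a: np.ndarray, b: np.ndarray) -> float:
    iu = np.triu_indices_from(a, k=1)
    diff = a[iu] - b[iu]
    return float(np.sqrt(np.mean(diff**2)))


def _repair_corr(R: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Clip eigenvalues at ``floor`` and renormalize to unit diagonal."""
    R = (R + R.T) / 2
    evals, evecs = np.linalg.eigh(R)
    if evals.min() < floor:
        R = (evecs * np.maximum(evals, floor)) @ evecs.T
    d = np.sqrt(np.clip(np.diag(R), floor, None))
    R = R / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return R


def _factor_root(R: np.ndarray) -> np.ndarray:
    """Principal-component root L with L Lᵀ = R (eigenvalues clipped at 0)."""
    evals, evecs = np.linalg.eigh(R)
    return evecs * np.sqrt(np.maximum(evals, 0.0))


def _safe_corr(x: np.ndarray) -> np.ndarray:
    """Correlation matrix with zeros in place of undefined entries."""
    with np.errstate(divide="ignore", invalid="ignore"):
        R = np.corrcoef(x, rowvar=False)
    R = np.nan_to_num(R, nan=0.0)
    np.fill_diagonal(R, 1.0)
    return R


def gen_data_matched(
    target_corr: np.ndarray,
    marginals: list[np.ndarray],
    rng: np.random.Generator,
    max_iter: int = 100,
    patience: int = 10,
) -> np.ndarray:
    """Generate an n×k dataset with given marginals and target correlations.

    Each output column is exactly a permutation of its supplied marginal
    vector.  Starting from an intermediate correlation matrix equal to the
    target, the algorithm (1) transforms a fixed matrix of standard-normal
    deviates to the intermediate correlation, (2) replaces each column by
    the rank-ordered marginal, (3) measures the achieved correlations,
    (4) adds the residual (target − achieved) to the intermediate matrix
    (repaired to a valid correlation matrix by eigenvalue clipping), and
    keeps the best iterate by off-diagonal RMSR, stopping early after
    ``patience`` non-improving iterations.
    """
    target_corr = np.asarray(target_corr, dtype=float)
    k = target_corr.shape[0]
    if target_corr.shape != (k, k):
        raise ValueError("target correlation matrix must be square")
    if not np.allclose(target_corr, target_corr.T, atol=1e-10):
        raise ValueError("target correlation matrix must be symmetric")
    if k < 2:
        raise ValueError("need at least 2 indicators")
    if len(marginals) != k:
        raise ValueError(f"{len(marginals)} marginals for {k} indicators")
    n = len(marginals[0])
    if any(len(m) != n for m in marginals):
        raise ValueError("marginal vectors must share one length")

    target = _repair_corr(target_corr.copy())
    sorted_marg = [np.sort(np.asarray(m, dtype=float)) for m in marginals]
    base = rng.standard_normal((n, k))
    R_int = target.copy()
    best_x: np.ndarray | None = None
    best_rmsr = np.inf
    stall = 0
    for _ in range(max_iter):
        Z = base @ _factor_root(R_int).T
        X = np.empty_like(Z)
        for j in range(k):
            ranks = np.argsort(np.argsort(Z[:, j], kind="stable"))
            X[:, j] = sorted_marg[j][ranks]
        achieved = _safe_corr(X)
        rmsr = _rmsr_offdiag(target, achieved)
        if rmsr < best_rmsr - 1e-12:
            best_rmsr = rmsr
            best_x = X
            stall = 0
        else:
            stall += 1
            if stall >= patience:
                break
        R_int = _repair_corr(R_int + (target - achieved))
    logger.debug("gen_data_matched: best RMSR %.4f", best_rmsr)
    assert best_x is not None
    return best_x


def _bootstrap_marginals(
    values: np.ndarray, rng: np.random.Generator, exact: bool
) -> list[np.ndarray]:
    n = values.shape[0]
    if exact:
        return [values[:, j].copy() for j in range(values.shape[1])]
    return [rng.choice(values[:, j], size=n, replace=True)
            for j in range(values.shape[1])]


def _ensemble_from_sets(
    structure: str,
    sets: list[dict[str, CurveSet]],
    base_rate: float | None = None,
) -> ComparisonEnsemble:
    methods = list(sets[0])
    curves = {m: [s[m].averaged_curve for s in sets] for m in methods}
    return ComparisonEnsemble(
        structure=structure, n_sets=len(sets), curves=curves,
        base_rate=base_rate,
    )


def generate_dimensional_comparison(
    matrix: IndicatorMatrix,
    n_sets: int,
    rng: np.random.Generator,
    settings: MethodSettings | None = None,
    lmode_grid: np.ndarray | None = None,
    max_iter: int = 100,
    exact_marginals: bool = False,
) -> ComparisonEnsemble:
    """Dimensional comparison ensemble: one continuous latent structure.

    Each simulated dataset matches the whole-sample correlation matrix and
    bootstrap-resampled marginals; taxometric curves are computed with the
    same settings as the empirical run.
    """
    if matrix.k < 3:
        raise ValueError("need at least 3 valid indicators")
    settings = settings or MethodSettings()
    target = _safe_corr(matrix.values)
    sets = []
    for _ in range(n_sets):
        marg = _bootstrap_marginals(matrix.values, rng, exact_marginals)
        sim = gen_data_matched(target, marg, rng, max_iter=max_iter)
        sim_matrix = IndicatorMatrix(sim, matrix.indicator_names)
        sets.append(compute_curves(sim_matrix, settings, rng, lmode_grid))
    return _ensemble_from_sets("dimensional", sets)


def generate_taxonic_comparison(
    matrix: IndicatorMatrix,
    base_rate: float,
    n_sets: int,
    rng: np.random.Generator,
    settings: MethodSettings | None = None,
    lmode_grid: np.ndarray | None = None,
    max_iter: int = 100,
    exact_marginals: bool = False,
) -> ComparisonEnsemble:
    """Taxonic comparison ensemble: a two-group mixture at ``base_rate``.

    Cases are split into putative taxon and complement by ranking on the
    standardized indicator total; each group's correlation matrix and
    marginals are reproduced separately and the groups concatenated, so
    every simulated dataset carries round(n·base_rate) taxon cases.
    """
    if matrix.k < 3:
        raise ValueError("need at least 3 valid indicators")
    settings = settings or MethodSettings()
    groups = classify_putative_groups(matrix, base_rate)
    blocks = [matrix.values[groups.taxon_index],
              matrix.values[groups.complement_index]]
    for block in blocks:
        if block.shape[0] < matrix.k + 2:
            raise ValueError(
                f"group of {block.shape[0]} cases too small to estimate "
                f"within-group correlations (need >= {matrix.k + 2})"
            )
    targets = [_safe_corr(b) for b in blocks]
    sets = []
    for _ in range(n_sets):
        parts = []
        for block, target in zip(blocks, targets):
            marg = _bootstrap_marginals(block, rng, exact_marginals)
            parts.append(gen_data_matched(target, marg, rng, max_iter=max_iter))
        sim = np.vstack(parts)
        sim_matrix = IndicatorMatrix(sim, matrix.indicator_names)
        sets.append(compute_curves(sim_matrix, settings, rng, lmode_grid))
    return _ensemble_from_sets("taxonic", sets, base_rate=base_rate)
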