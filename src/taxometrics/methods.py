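"""The three nonredundant coherent-cut-kinetics curve procedures.

MAMBAC (mean above minus below a cut) slides a cut along one indicator and
plots the difference of the output indicator's means above vs. below it;
the curve peaks for taxonic data and is dish-shaped for dimensional data.

MAXEIG generalizes maximum-covariance analysis: within overlapping windows
along an input indicator, the largest eigenvalue of the zero-diagonal
covariance matrix of the remaining indicators is plotted; taxonic data
produce a peak near the region where taxon and complement mix.

L-Mode extracts a single common factor and inspects the kernel density of
the factor scores: bimodality indicates taxonicity, and the left/right
mode locations m_L, m_R yield base-rate estimates
p_L = m_L²/(1+m_L²) and p_R = 1/(1+m_R²).

All procedures operate on an :class:`~taxometrics.matrix.IndicatorMatrix`
and return :class:`CurveSet` objects whose x grids depend only on the
sample size and settings, so curves from different datasets of equal n are
directly comparable point by point (the contract the comparison-curve fit
index relies on).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .matrix import IndicatorMatrix

__all__ = [
    "Curve",
    "CurveSet",
    "LModeResult",
    "MethodSettings",
    "mambac_curve",
    "mambac",
    "maxeig_curve",
    "maxeig",
    "lmode",
    "compute_curves",
    "estimate_base_rates",
]

logger = logging.getLogger(__name__)

METHODS = ("mambac", "maxeig", "lmode")


@dataclass
class Curve:
    """An x–y taxometric curve (cut position, window center, or score grid)."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if self.x.size < 2:
            raise ValueError("a curve needs at least 2 points")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("x must be strictly increasing")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("y must be finite")

    def __len__(self) -> int:
        return self.x.size


@dataclass
class CurveSet:
    """All panel curves of one method plus their pointwise average."""

    method: str
    panel_curves: list[Curve]
    averaged_curve: Curve
    base_rate_estimate: float | None = None
    extra: dict = field(default_factory=dict)


@dataclass
class LModeResult:
    """One-factor solution, factor-score density, and mode-based base rates."""

    loadings: np.ndarray
    scores: np.ndarray
    grid: np.ndarray
    density: np.ndarray
    m_left: float | None
    m_right: float | None
    p_left: float | None
    p_right: float | None
    p_hat: float | None

    @property
    def curve(self) -> Curve:
        return Curve(self.grid, self.density)


@dataclass
class MethodSettings:
    """Shared settings for the curve procedures.

    Defaults are the conventional choices: 50 MAMBAC cuts starting 25
    cases from each end with 10 tie-randomized replications; 50 MAXEIG
    windows with 90% overlap; 512 density grid points for L-Mode.
    """

    methods: tuple[str, ...] = METHODS
    n_cuts: int = 50
    end_offset: int = 25
    replications: int = 10
    n_windows: int = 50
    overlap: float = 0.9
    grid_points: int = 512

    def __post_init__(self) -> None:
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods {sorted(unknown)}")
        if not self.methods:
            raise ValueError("at least one method required")
        if not 0 <= self.overlap < 1:
            raise ValueError("overlap must lie in [0, 1)")


# ---------------------------------------------------------------------------
# MAMBAC


def _cut_positions(n: int, n_cuts: int, end_offset: int) -> np.ndarray:
    if n < 2 * end_offset + n_cuts:
        raise ValueError(
            f"n={n} too small for {n_cuts} cuts with end offset {end_offset}; "
            "lower n_cuts or end_offset"
        )
    pos = np.linspace(end_offset, n - end_offset, n_cuts)
    return np.round(pos).astype(int)


def mambac_curve(
    input_: np.ndarray,
    output: np.ndarray,
    n_cuts: int = 50,
    end_offset: int = 25,
    rng: np.random.Generator | None = None,
) -> Curve:
    """Mean-above-minus-below curve for one ordered indicator pair.

    Cases are sorted by the input indicator (ties broken by a random
    permutation when ``rng`` is given, else by stable order); at each of
    ``n_cuts`` cut positions evenly spaced between ``end_offset`` cases
    from either end, y = mean(output above cut) − mean(output below cut).
    x is the cut position in case-rank units.
    """
    input_ = np.asarray(input_, dtype=float)
    output = np.asarray(output, dtype=float)
    n = input_.size
    if output.size != n:
        raise ValueError("input and output lengths differ")
    cuts = _cut_positions(n, n_cuts, end_offset)
    if rng is not None:
        order = np.lexsort((rng.random(n), input_))
    else:
        order = np.argsort(input_, kind="stable")
    sorted_out = output[order]
    csum = np.concatenate([[0.0], np.cumsum(sorted_out)])
    below = csum[cuts] / cuts
    above = (csum[-1] - csum[cuts]) / (n - cuts)
    return Curve(cuts.astype(float), above - below)


def mambac(
    matrix: IndicatorMatrix,
    n_cuts: int = 50,
    end_offset: int = 25,
    replications: int = 10,
    rng: np.random.Generator | None = None,
) -> CurveSet:
    """MAMBAC over every ordered indicator pair (k(k−1) panels).

    Each panel is the mean over ``replications`` runs with re-randomized
    tie ordering (a single run when the input indicator is tie-free).  The
    averaged curve is the pointwise mean over panels; the base-rate
    estimate is the curve-end heuristic p = y_first/(y_first + y_last) on
    the raw averaged curve.  On a noiseless two-group mixture with the
    taxon at the high end, the left end of the curve tends to d·p and the
    right end to d·(1−p), so the ratio recovers p exactly; within-group
    variance attenuates it toward 0.5.
    """
    if matrix.k < 2:
        raise ValueError("MAMBAC needs at least 2 indicators")
    if rng is None:
        rng = np.random.default_rng()
    panels: list[Curve] = []
    for i in range(matrix.k):
        has_ties = np.unique(matrix.values[:, i]).size < matrix.n
        reps = replications if has_ties else 1
        for j in range(matrix.k):
            if i == j:
                continue
            ys = []
            for _ in range(reps):
                c = mambac_curve(
                    matrix.values[:, i], matrix.values[:, j],
                    n_cuts=n_cuts, end_offset=end_offset,
                    rng=rng if has_ties else None,
                )
                ys.append(c.y)
            panels.append(Curve(c.x, np.mean(ys, axis=0)))
    avg = Curve(panels[0].x, np.mean([p.y for p in panels], axis=0))
    denom = avg.y[0] + avg.y[-1]
    p_hat = float(avg.y[0] / denom) if denom > 0 else None
    if p_hat is not None and not 0 < p_hat < 1:
        p_hat = min(max(p_hat, 1e-3), 1 - 1e-3)
    return CurveSet("mambac", panels, avg, p_hat)


# ---------------------------------------------------------------------------
# MAXEIG


def _window_bounds(n: int, n_windows: int, overlap: float, min_size: int):
    size = int(round(n / (1 + (n_windows - 1) * (1 - overlap))))
    if size < min_size:
        raise ValueError(
            f"window size {size} below minimum {min_size}; "
            "lower n_windows or raise overlap"
        )
    if n_windows == 1:
        starts = np.array([0])
    else:
        starts = np.round(np.linspace(0, n - size, n_windows)).astype(int)
    return starts, size


def maxeig_curve(
    input_: np.ndarray,
    outputs: np.ndarray,
    n_windows: int = 50,
    overlap: float = 0.9,
) -> Curve:
    """Largest-eigenvalue curve along one input indicator.

    Cases are sorted by the input; ``n_windows`` equal-count windows with
    the given fractional overlap span the sorted order.  Within each
    window the covariance matrix of the output indicators has its diagonal
    zeroed and y is its largest eigenvalue (non-negative, because the
    matrix has zero trace).  x is the window center in case-rank units —
    a grid that depends only on n and the settings, so curves from
    datasets of equal size are comparable even when heavily tied scores
    would make window means of the input coincide.
    """
    input_ = np.asarray(input_, dtype=float)
    outputs = np.atleast_2d(np.asarray(outputs, dtype=float))
    if outputs.shape[0] != input_.size:
        outputs = outputs.T
    n, m = outputs.shape
    if n != input_.size:
        raise ValueError("input and outputs lengths differ")
    if m < 2:
        raise ValueError("MAXEIG needs at least 2 output indicators")
    starts, size = _window_bounds(n, n_windows, overlap, min_size=m + 2)
    order = np.argsort(input_, kind="stable")
    sorted_out = outputs[order]
    xs = starts + (size - 1) / 2.0
    ys = np.empty(len(starts))
    for w, s in enumerate(starts):
        cov = np.cov(sorted_out[s : s + size], rowvar=False, ddof=1)
        np.fill_diagonal(cov, 0.0)
        ys[w] = np.linalg.eigvalsh(cov)[-1]
    return Curve(xs, ys)


def maxeig(
    matrix: IndicatorMatrix,
    n_windows: int = 50,
    overlap: float = 0.9,
) -> CurveSet:
    """MAXEIG with each indicator taking a turn as the input (k panels).

    The base-rate estimate is the proportion of cases lying above the
    center of the peak window of the averaged curve.
    """
    if matrix.k < 3:
        raise ValueError("MAXEIG needs at least 3 indicators")
    panels: list[Curve] = []
    for i in range(matrix.k):
        outputs = np.delete(matrix.values, i, axis=1)
        panels.append(
            maxeig_curve(matrix.values[:, i], outputs, n_windows, overlap)
        )
    avg = Curve(panels[0].x, np.mean([p.y for p in panels], axis=0))
    peak_center = avg.x[int(np.argmax(avg.y))]
    p_hat = float((matrix.n - peak_center) / matrix.n)
    p_hat = min(max(p_hat, 1e-3), 1 - 1e-3)
    return CurveSet("maxeig", panels, avg, p_hat)


# ---------------------------------------------------------------------------
# L-Mode


def _principal_axis_loadings(R: np.ndarray, max_iter: int = 200,
                             tol: float = 1e-8) -> np.ndarray:
    """One-factor principal-axis loadings with iterated communalities."""
    try:
        smc = 1.0 - 1.0 / np.diag(np.linalg.inv(R))
    except np.linalg.LinAlgError:
        raise ValueError("correlation matrix is singular") from None
    h2 = np.clip(smc, 0.0, 0.995)
    loadings = np.zeros(R.shape[0])
    for _ in range(max_iter):
        Rr = R.copy()
        np.fill_diagonal(Rr, h2)
        evals, evecs = np.linalg.eigh(Rr)
        lam = evecs[:, -1] * np.sqrt(max(evals[-1], 0.0))
        new_h2 = np.clip(lam**2, 0.0, 0.995)
        if np.max(np.abs(new_h2 - h2)) < tol:
            h2 = new_h2
            loadings = lam
            break
        h2 = new_h2
        loadings = lam
    if loadings.sum() < 0:
        loadings = -loadings
    return loadings


def lmode(
    matrix: IndicatorMatrix,
    grid_points: int = 512,
    grid: np.ndarray | None = None,
) -> LModeResult:
    """Latent-mode factor analysis.

    A single factor is extracted by principal-axis factoring of the
    correlation matrix; regression-method factor scores are standardized
    and reflected so their skewness is non-negative (taxon on the right).
    A Gaussian kernel density (Silverman bandwidth) is evaluated on a
    uniform grid spanning the scores ±0.5 (or on a supplied grid, so that
    comparison datasets share the empirical grid).  The left mode m_L is
    the density argmax over grid points < 0 and the right mode m_R over
    grid points > 0 (outermost two grid points excluded to avoid boundary
    artifacts); base-rate estimates follow the two-point-mixture
    identities p_L = m_L²/(1+m_L²), p_R = 1/(1+m_R²), p = (p_L+p_R)/2.
    """
    if matrix.k < 3:
        raise ValueError("L-Mode needs at least 3 indicators")
    x = matrix.values
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant indicator; cannot factor-analyze")
    Z = (x - x.mean(axis=0)) / sd
    R = np.corrcoef(x, rowvar=False)
    loadings = _principal_axis_loadings(R)
    scores = Z @ np.linalg.solve(R, loadings)
    s_sd = scores.std(ddof=1)
    if s_sd == 0:
        raise ValueError("degenerate factor scores")
    scores = (scores - scores.mean()) / s_sd
    if stats.skew(scores) < 0:
        scores = -scores
        loadings = -loadings
    if grid is None:
        grid = np.linspace(scores.min() - 0.5, scores.max() + 0.5, grid_points)
    else:
        grid = np.asarray(grid, dtype=float)
    kde = stats.gaussian_kde(scores, bw_method="silverman")
    density = kde(grid)

    interior = slice(1, -1)
    gx = grid[interior]
    gy = density[interior]
    m_left = m_right = p_left = p_right = None
    left = gx < 0
    right = gx > 0
    if left.any():
        m_left = float(gx[left][np.argmax(gy[left])])
        p_left = m_left**2 / (1 + m_left**2)
    if right.any():
        m_right = float(gx[right][np.argmax(gy[right])])
        p_right = 1.0 / (1 + m_right**2)
    defined = [p for p in (p_left, p_right) if p is not None]
    if not defined:
        warnings.warn("no interior mode on either side; base rate undefined")
        p_hat = None
    else:
        if len(defined) == 1:
            warnings.warn(
                "mode missing on one side; base rate from the other side only"
            )
        p_hat = float(np.mean(defined))
    return LModeResult(
        loadings=loadings, scores=scores, grid=grid, density=density,
        m_left=m_left, m_right=m_right,
        p_left=p_left, p_right=p_right, p_hat=p_hat,
    )


def lmode_curveset(result: LModeResult) -> CurveSet:
    curve = result.curve
    return CurveSet("lmode", [curve], curve, result.p_hat,
                    extra={"lmode": result})


# ---------------------------------------------------------------------------
# Orchestration helpers


def compute_curves(
    matrix: IndicatorMatrix,
    settings: MethodSettings | None = None,
    rng: np.random.Generator | None = None,
    lmode_grid: np.ndarray | None = None,
) -> dict[str, CurveSet]:
    """Run the selected curve procedures with shared settings.

    ``lmode_grid`` pins the L-Mode density grid (used so that comparison
    datasets are evaluated on the empirical dataset's grid).
    """
    settings = settings or MethodSettings()
    out: dict[str, CurveSet] = {}
    if "mambac" in settings.methods:
        out["mambac"] = mambac(
            matrix, settings.n_cuts, settings.end_offset,
            settings.replications, rng,
        )
    if "maxeig" in settings.methods:
        out["maxeig"] = maxeig(matrix, settings.n_windows, settings.overlap)
    if "lmode" in settings.methods:
        out["lmode"] = lmode_curveset(
            lmode(matrix, settings.grid_points, lmode_grid)
        )
    return out


def estimate_base_rates(curve_sets: dict[str, CurveSet]) -> dict:
    """Per-method base-rate estimates and their unweighted mean.

    Methods with an undefined estimate are omitted from the mean with a
    warning.  Values are returned at full precision; reporting layers
    round to 2 decimals.
    """
    per_method = {m: cs.base_rate_estimate for m, cs in curve_sets.items()}
    defined = [v for v in per_method.values() if v is not None]
    if not defined:
        raise ValueError("no method produced a defined base-rate estimate")
    if len(defined) < len(per_method):
        warnings.warn("some base-rate estimates undefined; omitted from mean")
    return {"per_method": per_method, "mean": float(np.mean(defined))}
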