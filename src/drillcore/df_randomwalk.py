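"""Serial Monte-Carlo random-walk null for drilling-frequency series.

A DF profile along a core is serially autocorrelated, so a permutation
null would be far too liberal.  Instead the null model bootstraps the
observed first differences: each simulated series starts at the DF
observed at the core base and, level by level, adds a difference drawn
uniformly with replacement from the pool of observed adjacent-level
differences.  A step that would take DF negative is reversed (the
difference is subtracted instead of added).  The 10 000-series ensemble
yields per-level 95% confidence bands, a null distribution for the
maximum-t breakpoint statistic, and a null distribution of depth-DF rank
correlations.

The breakpoint statistic scans every split of the series into a lower
and an upper part (each at least ``min_group`` levels, default 3) and
takes the boundary maximising |t|, where t is the difference of group
mean DFs divided by its two-sample standard error (classical pooled SE
by default; Welch as an option).

Series are ordered deepest level first, so a positive t (lower-part mean
above upper-part mean) and a positive depth-DF rho both indicate an
upward *decline* in drilling predation.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from collections.abc import Sequence

import numpy as np

from ._ranks import spearman, spearman_rows
from .core_model import CoreDataset, DegenerateDataError, ValidationError
from .drilling_metrics import DFEstimate
from .predator_trend import TrendTestResult

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class DFSeries:
    """An ordered (deepest-first) DF series of included estimates."""

    increment_ids: tuple[str, ...]
    depths: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        depths = np.asarray(self.depths, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "depths", depths)
        object.__setattr__(self, "values", values)
        if not (len(self.increment_ids) == depths.size == values.size):
            raise ValidationError("increment_ids, depths and values must align")
        if depths.size >= 2 and not np.all(np.diff(depths) < 0):
            raise ValidationError("depths must be strictly decreasing (deepest first)")
        if np.any(values < 0) or not np.all(np.isfinite(values)):
            raise ValidationError("df values must be finite and non-negative")

    @property
    def n_levels(self) -> int:
        return int(self.values.size)

    @classmethod
    def from_estimates(
        cls, estimates: Sequence[DFEstimate], dataset: CoreDataset
    ) -> "DFSeries":
        """Build a series from the included estimates of one dataset."""
        increment_map = dataset.increment_map
        rows = []
        for est in estimates:
            if not est.included or est.df is None:
                continue
            inc = increment_map[(est.core_id, est.increment_id)]
            rows.append((inc.mid_depth_cm, est.increment_id, est.df))
        rows.sort(key=lambda r: -r[0])
        if not rows:
            raise DegenerateDataError("no included DF estimates to build a series")
        return cls(
            increment_ids=tuple(r[1] for r in rows),
            depths=np.array([r[0] for r in rows]),
            values=np.array([r[2] for r in rows]),
        )


def first_differences(series: DFSeries) -> np.ndarray:
    """Observed adjacent-level differences, base to top (shallower minus deeper)."""
    if series.n_levels < 2:
        raise ValidationError("need at least 2 levels to form first differences")
    return np.diff(series.values)


@dataclasses.dataclass
class RandomWalkEnsemble:
    """Simulated DF series with per-level 95% bands."""

    series_matrix: np.ndarray
    band_lower: np.ndarray
    band_upper: np.ndarray
    start_value: float
    first_diff_pool: np.ndarray
    seed: int | None
    n_iter: int


def simulate_ensemble(
    series: DFSeries,
    n_iter: int = 10_000,
    seed: int | None = None,
    random_start: bool = False,
    negative_rule: str = "reflect",
) -> RandomWalkEnsemble:
    """Simulate the first-difference bootstrap random-walk ensemble.

    Parameters
    ----------
    random_start:
        Start each walk at a value drawn uniformly from the observed
        series instead of the basal value (an alternative initialisation
        that should leave conclusions essentially unchanged).
    negative_rule:
        "reflect" (default) reverses the sign of a step that would take
        DF negative; "clamp" truncates at 0 instead.
    """
    if negative_rule not in ("reflect", "clamp"):
        raise ValidationError(f"unknown negative_rule {negative_rule!r}")
    pool = first_differences(series)
    if pool.size == 0:
        raise ValidationError("empty first-difference pool")
    n = series.n_levels
    rng = np.random.default_rng(seed)
    if random_start:
        starts = rng.choice(series.values, size=n_iter)
    else:
        starts = np.full(n_iter, series.values[0])
    steps = rng.choice(pool, size=(n_iter, n - 1))
    matrix = np.empty((n_iter, n))
    matrix[:, 0] = starts
    for j in range(1, n):
        step = steps[:, j - 1]
        proposal = matrix[:, j - 1] + step
        if negative_rule == "reflect":
            negative = proposal < 0
            proposal[negative] = matrix[negative, j - 1] - step[negative]
        else:
            np.maximum(proposal, 0.0, out=proposal)
        matrix[:, j] = proposal
    band_lower, band_upper = np.percentile(matrix, [2.5, 97.5], axis=0)
    return RandomWalkEnsemble(
        series_matrix=matrix,
        band_lower=band_lower,
        band_upper=band_upper,
        start_value=float(starts[0]) if not random_start else float("nan"),
        first_diff_pool=pool,
        seed=seed,
        n_iter=n_iter,
    )


# ---------------------------------------------------------------------------
# Maximum-t breakpoint search
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class BreakpointScan:
    """Best split of a series into lower and upper parts."""

    boundary_index: int  # levels 1..b (deepest-first) form the lower group
    t_observed: float
    tied: bool
    boundaries: tuple[int, ...]
    t_by_boundary: np.ndarray


def _split_t_matrix(
    matrix: np.ndarray, min_group: int = 3, welch: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """t statistics for every admissible split of every row.

    Returns (boundaries, T) where T[i, j] is the t statistic of row i at
    boundary boundaries[j] (lower group = first ``b`` entries).  A split
    with zero standard error gets t = 0.
    """
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    n = matrix.shape[1]
    if n < 2 * min_group:
        raise ValidationError(
            f"need at least {2 * min_group} levels for min_group={min_group}"
        )
    boundaries = np.arange(min_group, n - min_group + 1)
    cums = np.cumsum(matrix, axis=1)
    cums2 = np.cumsum(matrix**2, axis=1)
    total = cums[:, -1]
    total2 = cums2[:, -1]
    # cancellation in the sums-of-squares leaves O(sqrt(eps)*scale)
    # residue on (near-)constant groups; anything below this is a zero SE
    se_floor = 1e-7 * (np.abs(matrix).max(axis=1) + 1e-30)
    t_cols = []
    for b in boundaries:
        n1, n2 = b, n - b
        s1 = cums[:, b - 1]
        ss1 = np.clip(cums2[:, b - 1] - s1**2 / n1, 0.0, None)
        s2 = total - s1
        ss2 = np.clip(total2 - cums2[:, b - 1] - s2**2 / n2, 0.0, None)
        m1, m2 = s1 / n1, s2 / n2
        if welch:
            se = np.sqrt(ss1 / (n1 * (n1 - 1)) + ss2 / (n2 * (n2 - 1)))
        else:
            pooled = (ss1 + ss2) / (n1 + n2 - 2)
            se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
        with np.errstate(invalid="ignore", divide="ignore"):
            ok = se > se_floor
            t = np.where(ok, (m1 - m2) / np.where(ok, se, 1.0), 0.0)
        t_cols.append(t)
    return boundaries, np.column_stack(t_cols)


def max_t_breakpoint(
    series: DFSeries | np.ndarray, min_group: int = 3, welch: bool = False
) -> BreakpointScan:
    """Find the split boundary maximising |t| between lower and upper parts.

    ``boundary_index`` = b means the lower (deeper) group consists of
    levels 1..b of the deepest-first series.  Exactly tied |t| maxima
    are flagged and resolved to the smallest boundary.
    """
    values = series.values if isinstance(series, DFSeries) else np.asarray(series, float)
    boundaries, t_matrix = _split_t_matrix(values[None, :], min_group, welch)
    t_row = t_matrix[0]
    abs_t = np.abs(t_row)
    best = int(np.argmax(abs_t))
    tied = bool(np.count_nonzero(abs_t >= abs_t[best] - 1e-12) > 1)
    if tied:
        logger.info("tied |t| maxima; returning the smallest boundary")
    if abs_t[best] == 0.0:
        logger.info("all split t statistics are zero (no signal)")
    return BreakpointScan(
        boundary_index=int(boundaries[best]),
        t_observed=float(t_row[best]),
        tied=tied,
        boundaries=tuple(int(b) for b in boundaries),
        t_by_boundary=t_row,
    )


@dataclasses.dataclass
class BreakpointResult:
    """Observed max-t split tested against the random-walk ensemble null."""

    boundary_index: int
    boundary_depth_cm: float | None
    t_observed: float
    null_max_t: np.ndarray
    p: float
    significant_05: bool
    tied: bool

    def to_dict(self) -> dict:
        return {
            "boundary_index": self.boundary_index,
            "boundary_depth_cm": self.boundary_depth_cm,
            "t_observed": self.t_observed,
            "p": self.p,
            "significant_05": self.significant_05,
            "tied": self.tied,
        }


def breakpoint_significance(
    series: DFSeries,
    ensemble: RandomWalkEnsemble,
    min_group: int = 3,
    welch: bool = False,
) -> BreakpointResult:
    """Compare the observed max-|t| split with the ensemble null.

    The same admissible-boundary range is scanned on the observed series
    and on every simulated series.  p is the fraction of simulated
    max-|t| values reaching the observed one (floored at 1/n_iter).
    """
    if ensemble.series_matrix.shape[1] != series.n_levels:
        raise ValidationError("ensemble was not simulated from this series")
    scan = max_t_breakpoint(series, min_group=min_group, welch=welch)
    _, t_null = _split_t_matrix(ensemble.series_matrix, min_group, welch)
    null_max_t = np.abs(t_null).max(axis=1)
    exceed = int(np.count_nonzero(null_max_t >= abs(scan.t_observed) - 1e-12))
    p = max(exceed, 1) / ensemble.n_iter
    b = scan.boundary_index
    boundary_depth = float(0.5 * (series.depths[b - 1] + series.depths[b]))
    return BreakpointResult(
        boundary_index=b,
        boundary_depth_cm=boundary_depth,
        t_observed=scan.t_observed,
        null_max_t=null_max_t,
        p=p,
        significant_05=p < 0.05,
        tied=scan.tied,
    )


def df_depth_rho_test(
    series: DFSeries, ensemble: RandomWalkEnsemble
) -> TrendTestResult | None:
    """Depth-DF Spearman correlation tested against the ensemble null.

    Positive rho indicates an upward decrease in drilling predation.
    Returns None when the observed series is constant (rho undefined).
    """
    if ensemble.series_matrix.shape[1] != series.n_levels:
        raise ValidationError("ensemble was not simulated from this series")
    rho_obs = spearman(series.values, series.depths)
    if math.isnan(rho_obs):
        logger.warning("constant DF series; depth-DF correlation undefined")
        return None
    null_rhos = spearman_rows(ensemble.series_matrix, series.depths, fill=0.0)
    exceed = int(np.count_nonzero(np.abs(null_rhos) >= abs(rho_obs) - 1e-12))
    p = max(exceed, 1) / ensemble.n_iter
    return TrendTestResult(
        rho_observed=float(rho_obs),
        null_rhos=null_rhos,
        p_two_tailed=p,
        n_iter=ensemble.n_iter,
        seed=ensemble.seed,
        n_levels=series.n_levels,
        p_hat=None,
    )


def moving_average(values: np.ndarray, window: int = 5) -> np.ndarray:
    """Centred moving average over successive sets of adjacent levels."""
    values = np.asarray(values, dtype=float)
    if window < 1 or window > values.size:
        raise ValidationError(f"window {window} incompatible with {values.size} levels")
    return np.convolve(values, np.full(window, 1.0 / window), mode="valid")
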