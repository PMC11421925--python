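"""Monte-Carlo null model for vertical trends in predator abundance.

Drilling gastropods (naticids, muricids) are rare — typically well under
2% of the assemblage — so their stratigraphic trend is tested against a
sampling null rather than eyeballed: the observed Spearman rank
correlation between per-level relative predator abundance and core depth
is compared with correlations from simulated cores in which predators
are drawn binomially at every level with a constant probability equal to
their overall relative frequency, using the actual per-level sample
sizes.  Depth is positive downward, so a positive rho means predator
abundance declines toward the core top.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from collections.abc import Sequence

import numpy as np

from ._ranks import spearman, spearman_rows
from .core_model import CoreDataset, DegenerateDataError, ValidationError
from .drilling_metrics import row_individuals

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class LevelAbundance:
    """Specimen totals for one core level (increment)."""

    increment_id: str
    mid_depth_cm: float
    n_total: int
    n_predators: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_predators <= self.n_total:
            raise ValidationError(
                f"{self.increment_id}: n_predators={self.n_predators} outside "
                f"[0, {self.n_total}]"
            )

    @property
    def relative_abundance(self) -> float:
        return self.n_predators / self.n_total if self.n_total else math.nan


@dataclasses.dataclass
class TrendTestResult:
    """Observed rank correlation against a Monte-Carlo null distribution."""

    rho_observed: float
    null_rhos: np.ndarray
    p_two_tailed: float
    n_iter: int
    seed: int | None
    n_levels: int
    p_hat: float | None = None

    def to_dict(self) -> dict:
        """JSON-ready summary (without the raw null draws)."""
        return {
            "rho_observed": self.rho_observed,
            "p_two_tailed": self.p_two_tailed,
            "n_iter": self.n_iter,
            "seed": self.seed,
            "n_levels": self.n_levels,
            "p_hat": self.p_hat,
        }


def levels_from_dataset(dataset: CoreDataset) -> list[LevelAbundance]:
    """Per-increment total and predator individual counts.

    Bivalve individuals are reconstructed with the valve correction and
    the level totals rounded to whole specimens (the binomial null needs
    integer trial counts).  Levels with no individuals are dropped with
    a warning.
    """
    out: list[LevelAbundance] = []
    by_increment = dataset.counts_by_increment()
    for inc in dataset.increments:
        rows = by_increment[(inc.core_id, inc.increment_id)]
        total = round(sum(row_individuals(row) for row in rows))
        predators = round(
            sum(row_individuals(row) for row in rows if row.is_predator)
        )
        if total == 0:
            logger.warning(
                "dropping empty level %s/%s", inc.core_id, inc.increment_id
            )
            continue
        out.append(
            LevelAbundance(
                increment_id=inc.increment_id,
                mid_depth_cm=inc.mid_depth_cm,
                n_total=total,
                n_predators=min(predators, total),
            )
        )
    return out


def observed_predator_rho(levels: Sequence[LevelAbundance]) -> float:
    """Spearman rho of relative predator abundance vs depth.

    Returns NaN (with a log message) when every level has the same
    relative abundance, in which case the correlation is undefined.
    """
    usable = [lv for lv in levels if lv.n_total > 0]
    if len(usable) < 3:
        raise ValidationError("need at least 3 non-empty levels")
    abundances = np.array([lv.relative_abundance for lv in usable])
    depths = np.array([lv.mid_depth_cm for lv in usable])
    rho = spearman(abundances, depths)
    if math.isnan(rho):
        logger.warning(
            "predator relative abundance is constant across levels; "
            "rank correlation undefined"
        )
    return rho


def predator_null_test(
    levels: Sequence[LevelAbundance],
    n_iter: int = 10_000,
    seed: int | None = None,
) -> TrendTestResult:
    """Two-tailed Monte-Carlo test of a vertical predator-abundance trend.

    Each iteration draws, for every level, a binomial predator count with
    the level's actual sample size and a constant success probability
    equal to the overall predator frequency across the tested levels.
    The p-value is the fraction of iterations whose |rho| reaches the
    observed |rho| (ties count as exceedances) and is floored at
    ``1/n_iter``.  Results are bit-reproducible for a given seed.
    """
    usable = [lv for lv in levels if lv.n_total > 0]
    if len(usable) < len(levels):
        logger.warning("dropped %d empty levels", len(levels) - len(usable))
    if len(usable) < 3:
        raise ValidationError("need at least 3 non-empty levels")
    n_totals = np.array([lv.n_total for lv in usable], dtype=int)
    depths = np.array([lv.mid_depth_cm for lv in usable])
    p_hat = sum(lv.n_predators for lv in usable) / n_totals.sum()
    if not 0.0 < p_hat < 1.0:
        raise DegenerateDataError(
            f"overall predator frequency {p_hat} is degenerate; the "
            "constant-abundance null cannot be simulated"
        )
    rho_obs = observed_predator_rho(usable)
    if math.isnan(rho_obs):
        raise DegenerateDataError(
            "observed relative abundances are constant; trend test inapplicable"
        )
    rng = np.random.default_rng(seed)
    sims = rng.binomial(n_totals, p_hat, size=(n_iter, len(usable)))
    rel = sims / n_totals
    null_rhos = spearman_rows(rel, depths, fill=0.0)
    exceed = int(np.count_nonzero(np.abs(null_rhos) >= abs(rho_obs) - 1e-12))
    p = max(exceed, 1) / n_iter
    return TrendTestResult(
        rho_observed=float(rho_obs),
        null_rhos=null_rhos,
        p_two_tailed=p,
        n_iter=n_iter,
        seed=seed,
        n_levels=len(usable),
        p_hat=float(p_hat),
    )
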