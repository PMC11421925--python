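"""Community-composition statistics for increment-level assemblages.

The composition battery mirrors standard community-ecology practice:
per-increment individual counts are converted to proportional
abundances, square-root transformed, and turned into a Bray-Curtis
dissimilarity matrix.  On top of that sit non-metric multidimensional
scaling (k = 2, Kruskal stress-1), one-way PERMANOVA with permutation
p-values, a Kruskal-Wallis / pairwise-Wilcoxon battery for DF by
temporal unit, and distance-based redundancy analysis (PCoA followed by
RDA of the retained axis scores on a single constraint such as DF).
"""

from __future__ import annotations

import dataclasses
import inspect
import itertools
import logging
import math
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import MDS

from .core_model import (
    CoreDataset,
    DegenerateDataError,
    ValidationError,
)
from .drilling_metrics import row_individuals

logger = logging.getLogger(__name__)

# scikit-learn is renaming MDS's non-metric switch (metric -> metric_mds)
_MDS_METRIC_KW = (
    "metric_mds"
    if "metric_mds" in inspect.signature(MDS.__init__).parameters
    else "metric"
)


@dataclasses.dataclass
class CommunityMatrix:
    """Samples (increments) x taxa proportional-abundance matrix."""

    data: pd.DataFrame
    transform: str = "none"

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(str(i) for i in self.data.index)


def to_proportions(
    dataset: CoreDataset, min_n: float | None = None
) -> CommunityMatrix:
    """Per-increment proportional abundances (rows sum to 1).

    Bivalve individuals are reconstructed with the valve correction.
    Empty increments are excluded with a warning; ``min_n`` additionally
    drops increments below a minimum individual count.
    """
    records: dict[str, dict[str, float]] = {}
    by_increment = dataset.counts_by_increment()
    for inc in dataset.increments:
        rows = by_increment[(inc.core_id, inc.increment_id)]
        totals = {row.taxon: row_individuals(row) for row in rows}
        total = sum(totals.values())
        if total <= 0:
            logger.warning(
                "excluding empty increment %s/%s", inc.core_id, inc.increment_id
            )
            continue
        if min_n is not None and total < min_n:
            logger.info(
                "excluding increment %s with %.1f individuals (< %s)",
                inc.increment_id,
                total,
                min_n,
            )
            continue
        records[inc.increment_id] = {t: v / total for t, v in totals.items() if v > 0}
    frame = pd.DataFrame.from_dict(records, orient="index").fillna(0.0)
    frame = frame.reindex(sorted(frame.columns), axis=1)
    return CommunityMatrix(data=frame, transform="none")


def sqrt_transform(matrix: CommunityMatrix) -> CommunityMatrix:
    """Element-wise square root of the abundance matrix."""
    if (matrix.data.values < 0).any():
        raise ValidationError("negative abundances cannot be sqrt-transformed")
    return CommunityMatrix(data=np.sqrt(matrix.data), transform="sqrt")


@dataclasses.dataclass
class DissimilarityMatrix:
    """Square symmetric Bray-Curtis dissimilarity matrix."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise ValidationError("dissimilarity matrix must be square and match ids")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0.0):
            raise ValidationError("dissimilarity matrix must be symmetric, zero-diagonal")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.ids)


def bray_curtis(matrix: CommunityMatrix) -> DissimilarityMatrix:
    """Bray-Curtis dissimilarities between samples.

    d(x, y) = 1 - 2 sum(min(x_t, y_t)) / sum(x_t + y_t); identical rows
    give 0, rows with disjoint support give 1.
    """
    X = matrix.data.to_numpy(dtype=float)
    if np.any(X.sum(axis=1) <= 0):
        raise DegenerateDataError("all-zero sample rows make Bray-Curtis undefined")
    values = squareform(pdist(X, metric="braycurtis"))
    return DissimilarityMatrix(ids=matrix.sample_ids, values=values)


# ---------------------------------------------------------------------------
# Principal coordinates
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class PCoAResult:
    """Principal-coordinate decomposition of a dissimilarity matrix."""

    coordinates: np.ndarray  # n x m, axes scaled to sqrt(eigenvalue)
    eigenvalues: np.ndarray  # positive eigenvalues, descending
    positive_inertia: float
    negative_inertia: float


def pcoa(dissim: DissimilarityMatrix) -> PCoAResult:
    """Gower-centred eigendecomposition; negative-eigenvalue axes dropped."""
    D2 = dissim.values**2
    n = dissim.n
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ D2 @ J
    eigenvalues, vectors = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigenvalues)[::-1]
    eigenvalues = eigenvalues[order]
    vectors = vectors[:, order]
    tol = max(1e-12, 1e-9 * abs(eigenvalues[0])) if n else 0.0
    positive = eigenvalues > tol
    coords = vectors[:, positive] * np.sqrt(eigenvalues[positive])
    return PCoAResult(
        coordinates=coords,
        eigenvalues=eigenvalues[positive],
        positive_inertia=float(eigenvalues[positive].sum()),
        negative_inertia=float(eigenvalues[eigenvalues < -tol].sum()),
    )


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class OrdinationResult:
    """NMDS configuration with Kruskal stress-1."""

    coordinates: pd.DataFrame
    stress: float
    converged: bool
    n_restarts: int
    seed: int | None


def nmds(
    dissim: DissimilarityMatrix,
    k: int = 2,
    n_restarts: int = 4,
    max_iter: int = 300,
    eps: float = 1e-9,
    seed: int | None = None,
) -> OrdinationResult:
    """Non-metric multidimensional scaling minimising Kruskal stress-1.

    The best configuration over ``n_restarts`` random starts plus one
    metric (principal-coordinate) start is returned.  The result is
    canonically oriented — centred, rotated to principal axes, with each
    axis's sign fixed by its heaviest-loading sample — so repeated runs
    with the same seed are reproducible coordinates, not just shapes.
    """
    n = dissim.n
    if n < k + 2:
        raise ValidationError(f"need at least {k + 2} samples for k={k} NMDS")
    rng = np.random.default_rng(seed)
    metric_start = pcoa(dissim).coordinates
    if metric_start.shape[1] < k:
        pad = np.zeros((n, k - metric_start.shape[1]))
        metric_start = np.hstack([metric_start, pad])
    inits = [metric_start[:, :k]]
    inits += [rng.normal(size=(n, k)) for _ in range(n_restarts)]

    best_stress = math.inf
    best_coords = None
    best_n_iter = max_iter
    for init in inits:
        model = MDS(
            n_components=k,
            dissimilarity="precomputed",
            n_init=1,
            max_iter=max_iter,
            eps=eps,
            normalized_stress=True,
            **{_MDS_METRIC_KW: False},
        )
        model.fit(dissim.values, init=init)
        if model.stress_ < best_stress:
            best_stress = float(model.stress_)
            best_coords = model.embedding_
            best_n_iter = int(model.n_iter_)

    coords = best_coords - best_coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords, full_matrices=False)
    coords = coords @ vt.T
    for j in range(coords.shape[1]):
        heaviest = int(np.argmax(np.abs(coords[:, j])))
        if coords[heaviest, j] < 0:
            coords[:, j] = -coords[:, j]
    frame = pd.DataFrame(
        coords,
        index=list(dissim.ids),
        columns=[f"axis{i + 1}" for i in range(k)],
    )
    return OrdinationResult(
        coordinates=frame,
        stress=best_stress,
        converged=best_n_iter < max_iter,
        n_restarts=n_restarts,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class PermanovaResult:
    """One-way PERMANOVA pseudo-F with a permutation p-value."""

    factor: str
    pseudo_F: float
    p_perm: float
    n_perm: int
    seed: int | None
    method: str = "mc"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _permanova_F(D2: np.ndarray, labels: np.ndarray) -> float:
    n = D2.shape[0]
    ss_total = D2.sum() / (2.0 * n)
    ss_within = 0.0
    groups = np.unique(labels)
    for g in groups:
        idx = np.flatnonzero(labels == g)
        ss_within += D2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    a = groups.size
    ss_between = ss_total - ss_within
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def permanova(
    dissim: DissimilarityMatrix,
    grouping: Sequence,
    n_perm: int = 9_999,
    seed: int | None = None,
    strata: Sequence | None = None,
    exact: bool = False,
    factor: str = "group",
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a dissimilarity matrix.

    The pseudo-F partitions the total sum of squared dissimilarities
    into between- and within-group parts (Gower-centred identity).  With
    ``exact=True`` all label permutations are enumerated (only feasible
    for small n) and p is the exact fraction of permutations with F at
    least the observed; otherwise p = (1 + b)/(1 + B) over ``n_perm``
    random permutations, optionally restricted within ``strata``.
    """
    labels = np.asarray([str(g) for g in grouping])
    if labels.size != dissim.n:
        raise ValidationError("grouping length does not match dissimilarity matrix")
    unique, counts = np.unique(labels, return_counts=True)
    if unique.size < 2:
        raise DegenerateDataError("grouping must define at least two groups")
    if counts.min() < 2:
        raise DegenerateDataError("every group needs at least two samples")
    D2 = dissim.values**2
    F_obs = _permanova_F(D2, labels)

    if exact:
        if dissim.n > 10:
            raise ValidationError("exact enumeration limited to n <= 10 samples")
        count = 0
        total = 0
        for perm in itertools.permutations(range(dissim.n)):
            F = _permanova_F(D2, labels[list(perm)])
            count += F >= F_obs - 1e-12
            total += 1
        return PermanovaResult(
            factor=factor,
            pseudo_F=float(F_obs),
            p_perm=count / total,
            n_perm=total,
            seed=None,
            method="exact",
        )

    rng = np.random.default_rng(seed)
    if strata is not None:
        strata = np.asarray([str(s) for s in strata])
        if strata.size != dissim.n:
            raise ValidationError("strata length does not match dissimilarity matrix")
        stratum_indices = [np.flatnonzero(strata == s) for s in np.unique(strata)]
    exceed = 0
    perm_labels = labels.copy()
    for _ in range(n_perm):
        if strata is None:
            perm_labels = labels[rng.permutation(dissim.n)]
        else:
            perm_labels = labels.copy()
            for idx in stratum_indices:
                perm_labels[idx] = labels[idx[rng.permutation(idx.size)]]
        exceed += _permanova_F(D2, perm_labels) >= F_obs - 1e-12
    p = (1 + exceed) / (1 + n_perm)
    return PermanovaResult(
        factor=factor,
        pseudo_F=float(F_obs),
        p_perm=p,
        n_perm=n_perm,
        seed=seed,
        method="mc",
    )


# ---------------------------------------------------------------------------
# DF-by-unit rank-test battery
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class KWBatteryResult:
    """Kruskal-Wallis H with Bonferroni-corrected pairwise Wilcoxon tests."""

    h_statistic: float
    dof: int
    p_value: float
    pairwise: dict[tuple[str, str], float]
    dropped: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "h_statistic": self.h_statistic,
            "dof": self.dof,
            "p_value": self.p_value,
            "pairwise": {f"{a}|{b}": p for (a, b), p in sorted(self.pairwise.items())},
            "dropped": list(self.dropped),
        }


def df_by_unit_tests(values_by_unit: Mapping[str, Sequence[float]]) -> KWBatteryResult:
    """Test DF differences between temporal units.

    Tie-corrected Kruskal-Wallis H (chi-squared approximation, df =
    groups - 1) followed by all pairwise two-sided Wilcoxon rank-sum
    tests with Bonferroni correction (p multiplied by the number of
    comparisons, capped at 1).  Units with fewer than two values are
    dropped with a warning.
    """
    kept: dict[str, np.ndarray] = {}
    dropped: list[str] = []
    for unit, values in values_by_unit.items():
        arr = np.asarray(list(values), dtype=float)
        if arr.size < 2:
            logger.warning("dropping unit %s with %d value(s)", unit, arr.size)
            dropped.append(str(unit))
        else:
            kept[str(unit)] = arr
    if len(kept) < 2:
        raise DegenerateDataError("need at least two units with >= 2 values each")
    groups = list(kept.values())
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        logger.warning("all DF values identical; H reported as 0")
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*groups)
    names = list(kept.keys())
    n_comparisons = len(names) * (len(names) - 1) // 2
    pairwise: dict[tuple[str, str], float] = {}
    for a, b in itertools.combinations(names, 2):
        if np.all(kept[a] == kept[a][0]) and np.all(kept[b] == kept[b][0]) and (
            kept[a][0] == kept[b][0]
        ):
            raw = 1.0
        else:
            raw = float(
                stats.mannwhitneyu(kept[a], kept[b], alternative="two-sided").pvalue
            )
        pairwise[(a, b)] = min(1.0, raw * n_comparisons)
    return KWBatteryResult(
        h_statistic=float(h),
        dof=len(names) - 1,
        p_value=float(p),
        pairwise=pairwise,
        dropped=tuple(dropped),
    )


# ---------------------------------------------------------------------------
# Distance-based RDA
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class DbRDAResult:
    """Distance-based redundancy analysis of composition on one constraint."""

    f_statistic: float
    p_perm: float
    constrained_fraction: float
    n_perm: int
    seed: int | None
    retained_axes: int
    retained_inertia_fraction: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def dbrda(
    dissim: DissimilarityMatrix,
    constraint: Sequence[float],
    n_perm: int = 999,
    seed: int | None = None,
    keep_fraction: float = 1.0,
) -> DbRDAResult:
    """PCoA of the dissimilarity matrix followed by RDA on one constraint.

    Negative-eigenvalue axes are dropped; the retained positive axes
    cover at least ``keep_fraction`` of the positive inertia (all of it
    by default).  F = SS_fit / (SS_resid / (n - 2)) for the single
    constraint; significance by permutation of the constraint values
    with the (1 + b)/(1 + B) convention.
    """
    x = np.asarray(list(constraint), dtype=float)
    n = dissim.n
    if x.size != n:
        raise ValidationError("constraint length does not match dissimilarity matrix")
    if n < 4:
        raise ValidationError(
            "need at least 4 samples (insufficient residual degrees of freedom)"
        )
    if np.all(x == x[0]):
        raise DegenerateDataError("constant constraint carries no information")
    pc = pcoa(dissim)
    cum = np.cumsum(pc.eigenvalues) / pc.positive_inertia
    m = int(np.searchsorted(cum, keep_fraction - 1e-12) + 1)
    Y = pc.coordinates[:, :m]
    retained_fraction = float(cum[m - 1])
    logger.info(
        "dbRDA retains %d PCoA axes covering %.1f%% of positive inertia",
        m,
        100 * retained_fraction,
    )

    xc = x - x.mean()
    xx = float(xc @ xc)
    ss_total = float((Y**2).sum())

    def ss_fit(x_rows: np.ndarray) -> np.ndarray:
        proj = x_rows @ Y  # (..., m)
        return (proj**2).sum(axis=-1) / xx

    ss_obs = float(ss_fit(xc))
    F_obs = ss_obs / ((ss_total - ss_obs) / (n - 2))

    rng = np.random.default_rng(seed)
    perms = np.empty((n_perm, n))
    for i in range(n_perm):
        perms[i] = xc[rng.permutation(n)]
    ss_perm = ss_fit(perms)
    F_perm = ss_perm / ((ss_total - ss_perm) / (n - 2))
    p = (1 + int(np.count_nonzero(F_perm >= F_obs - 1e-12))) / (1 + n_perm)
    return DbRDAResult(
        f_statistic=float(F_obs),
        p_perm=p,
        constrained_fraction=ss_obs / ss_total,
        n_perm=n_perm,
        seed=seed,
        retained_axes=m,
        retained_inertia_fraction=retained_fraction,
    )
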