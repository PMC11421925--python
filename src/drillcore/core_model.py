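"""Core data model for stratigraphic death-assemblage datasets.

A sediment core is sliced into depth increments; within each increment,
molluscan specimens are counted per taxon with the skeletal bookkeeping
needed for drilling-frequency estimation: bivalves are recorded as
articulated specimens plus loose left and right valves, univalved shells
(gastropods, scaphopods) as whole shells, and drill holes as drilled
valves/shells.  This module holds the validated record types, the CSV
readers/writers, and the pooling and binning rules that turn raw counts
into analysis-ready series:

* pooling of replicate cores from the same station,
* pooling of adjacent thin surface increments into thicker ones,
* assignment of increments to temporal units from their age estimates.

Depths are in cm below the sediment-water interface, positive downward;
an increment's representative depth is its midpoint.  Ages are stored
internally as calendar years CE (years BP in input files are converted
as 1950 - BP).
"""

from __future__ import annotations

import dataclasses
import enum
import logging
import math
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

_DEPTH_TOL = 1e-6


class DrillcoreError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(DrillcoreError):
    """An input table is missing required columns or uses unknown codes."""


class ValidationError(DrillcoreError):
    """A record violates a data invariant."""


class AlignmentError(DrillcoreError):
    """Datasets that must share a depth grid do not."""


class PairingError(DrillcoreError):
    """Surface increments cannot be paired for pooling."""


class DegenerateDataError(DrillcoreError):
    """The data are degenerate for the requested statistic."""


class DrillcoreWarning(UserWarning):
    """Non-fatal data oddity (e.g. a drilling frequency above 1)."""


class Group(str, enum.Enum):
    """Skeletal group of a taxon."""

    BIVALVE = "bivalve"
    GASTROPOD = "gastropod"
    SCAPHOPOD = "scaphopod"


#: groups recorded as whole shells rather than valves
UNIVALVED = (Group.GASTROPOD, Group.SCAPHOPOD)


class TemporalUnit(str, enum.Enum):
    """The four age bins used throughout the analyses (oldest first)."""

    HOLOCENE = "holocene"
    C17_EARLY_C19 = "c17_early_c19"
    LATE_C19_EARLY_C20 = "late_c19_early_c20"
    LATE_C20_C21 = "late_c20_c21"


#: ordered tuple of the temporal units, oldest first
UNIT_ORDER: tuple[TemporalUnit, ...] = tuple(TemporalUnit)

#: default calendar-year cuts between successive temporal units (CE).
#: The unit names, not the cut years, are fixed by the study design;
#: these defaults are user-overridable everywhere they are consumed.
DEFAULT_UNIT_BOUNDARIES: tuple[float, float, float] = (1600.0, 1850.0, 1950.0)


@dataclasses.dataclass(frozen=True)
class TaxonIncrementCount:
    """Specimen counts for one taxon in one core increment.

    For bivalves the individual count is reconstructed downstream as
    ``(n_left + n_right) / 2 + n_articulated``; ``n_drilled`` counts
    drilled valves.  For univalved taxa ``n_whole`` counts shells and
    ``n_drilled`` counts drilled shells.
    """

    core_id: str
    increment_id: str
    taxon: str
    group: Group
    is_predator: bool = False
    n_articulated: int = 0
    n_left: int = 0
    n_right: int = 0
    n_whole: int = 0
    n_drilled: int = 0

    def __post_init__(self) -> None:
        for field in ("n_articulated", "n_left", "n_right", "n_whole", "n_drilled"):
            value = getattr(self, field)
            if not isinstance(value, (int,)) or isinstance(value, bool):
                if isinstance(value, float) and value.is_integer():
                    object.__setattr__(self, field, int(value))
                    value = int(value)
                else:
                    raise ValidationError(
                        f"{self.taxon}/{self.increment_id}: {field}={value!r} is not an integer"
                    )
            if value < 0:
                raise ValidationError(
                    f"{self.taxon}/{self.increment_id}: {field}={value} is negative"
                )
        if self.group is Group.BIVALVE:
            if self.n_whole != 0:
                raise ValidationError(
                    f"{self.taxon}/{self.increment_id}: bivalve row with n_whole={self.n_whole}"
                )
            cap = self.n_left + self.n_right + 2 * self.n_articulated
            if self.n_drilled > cap:
                raise ValidationError(
                    f"{self.taxon}/{self.increment_id}: n_drilled={self.n_drilled} exceeds "
                    f"available valves ({cap})"
                )
        else:
            if self.n_articulated or self.n_left or self.n_right:
                raise ValidationError(
                    f"{self.taxon}/{self.increment_id}: valve counts on a {self.group.value} row"
                )
            if self.n_drilled > self.n_whole:
                raise ValidationError(
                    f"{self.taxon}/{self.increment_id}: n_drilled={self.n_drilled} exceeds "
                    f"n_whole={self.n_whole}"
                )


@dataclasses.dataclass(frozen=True)
class Increment:
    """One depth slice of a core, with its age estimate (year CE)."""

    core_id: str
    increment_id: str
    top_depth_cm: float
    bottom_depth_cm: float
    age_estimate: float | None = None
    temporal_unit: TemporalUnit | None = None

    def __post_init__(self) -> None:
        if not self.top_depth_cm < self.bottom_depth_cm:
            raise ValidationError(
                f"{self.core_id}/{self.increment_id}: top depth {self.top_depth_cm} "
                f"not above bottom depth {self.bottom_depth_cm}"
            )

    @property
    def mid_depth_cm(self) -> float:
        return 0.5 * (self.top_depth_cm + self.bottom_depth_cm)

    @property
    def thickness_cm(self) -> float:
        return self.bottom_depth_cm - self.top_depth_cm


@dataclasses.dataclass
class CoreDataset:
    """A validated collection of increments and per-taxon counts.

    Increments are kept sorted by (core_id, top depth), i.e. within a
    core the shallowest increment comes first and the deepest last.
    """

    increments: list[Increment]
    counts: list[TaxonIncrementCount]
    metadata: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.increments = sorted(
            self.increments, key=lambda inc: (inc.core_id, inc.top_depth_cm)
        )
        self._validate()

    def _validate(self) -> None:
        keys = set()
        for inc in self.increments:
            key = (inc.core_id, inc.increment_id)
            if key in keys:
                raise ValidationError(f"duplicate increment {key}")
            keys.add(key)
        # non-overlap and age monotonicity within each core
        by_core: dict[str, list[Increment]] = {}
        for inc in self.increments:
            by_core.setdefault(inc.core_id, []).append(inc)
        for core_id, incs in by_core.items():
            for upper, lower in zip(incs, incs[1:]):
                if lower.top_depth_cm < upper.bottom_depth_cm - _DEPTH_TOL:
                    raise ValidationError(
                        f"{core_id}: increments {upper.increment_id} and "
                        f"{lower.increment_id} overlap"
                    )
                if (
                    upper.age_estimate is not None
                    and lower.age_estimate is not None
                    and lower.age_estimate > upper.age_estimate + 1e-9
                ):
                    raise ValidationError(
                        f"{core_id}: age increases upward between "
                        f"{lower.increment_id} and {upper.increment_id}"
                    )
        seen_rows = set()
        for row in self.counts:
            key = (row.core_id, row.increment_id)
            if key not in keys:
                raise ValidationError(
                    f"count row {row.taxon!r} references unknown increment {key}"
                )
            row_key = (row.core_id, row.increment_id, row.taxon)
            if row_key in seen_rows:
                raise ValidationError(f"duplicate count row {row_key}")
            seen_rows.add(row_key)

    # -- convenience accessors -------------------------------------------

    @property
    def increment_map(self) -> dict[tuple[str, str], Increment]:
        return {(inc.core_id, inc.increment_id): inc for inc in self.increments}

    def counts_for(self, core_id: str, increment_id: str) -> list[TaxonIncrementCount]:
        return [
            row
            for row in self.counts
            if row.core_id == core_id and row.increment_id == increment_id
        ]

    def counts_by_increment(self) -> dict[tuple[str, str], list[TaxonIncrementCount]]:
        out: dict[tuple[str, str], list[TaxonIncrementCount]] = {
            (inc.core_id, inc.increment_id): [] for inc in self.increments
        }
        for row in self.counts:
            out[(row.core_id, row.increment_id)].append(row)
        return out

    def taxa(self) -> list[str]:
        return sorted({row.taxon for row in self.counts})

    def core_ids(self) -> list[str]:
        seen: list[str] = []
        for inc in self.increments:
            if inc.core_id not in seen:
                seen.append(inc.core_id)
        return seen


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

COUNT_COLUMNS = [
    "core_id",
    "increment_id",
    "taxon",
    "group",
    "is_predator",
    "n_articulated",
    "n_left",
    "n_right",
    "n_whole",
    "n_drilled",
]

INCREMENT_COLUMNS = [
    "core_id",
    "increment_id",
    "top_depth_cm",
    "bottom_depth_cm",
    "age_estimate",
    "age_convention",
]


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    if isinstance(value, str):
        lowered = value.strip().lower()
        if lowered in ("true", "1", "yes"):
            return True
        if lowered in ("false", "0", "no"):
            return False
        raise ValidationError(f"cannot parse boolean value {value!r}")
    try:
        return bool(int(value))
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"cannot parse boolean value {value!r}") from exc


def _check_columns(frame: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [col for col in required if col not in frame.columns]
    if missing:
        raise SchemaError(f"{what} table is missing column(s): {', '.join(missing)}")


def read_core_table(
    counts_path: str | Path,
    increments_path: str | Path,
    metadata: Mapping | None = None,
) -> CoreDataset:
    """Read a counts CSV and an increments CSV into a validated dataset.

    The increments table carries an ``age_convention`` column ("CE" or
    "BP") per row; ages are converted to calendar years CE internally.
    """
    counts_frame = pd.read_csv(counts_path)
    _check_columns(counts_frame, COUNT_COLUMNS, "counts")
    increments_frame = pd.read_csv(increments_path)
    _check_columns(increments_frame, INCREMENT_COLUMNS, "increments")

    increments: list[Increment] = []
    for _, row in increments_frame.iterrows():
        age = row["age_estimate"]
        if pd.isna(age):
            age_ce = None
        else:
            convention = str(row["age_convention"]).strip().upper()
            if convention == "CE":
                age_ce = float(age)
            elif convention == "BP":
                age_ce = 1950.0 - float(age)
            else:
                raise SchemaError(
                    f"unknown age_convention {row['age_convention']!r} "
                    f"for increment {row['increment_id']!r}"
                )
        increments.append(
            Increment(
                core_id=str(row["core_id"]),
                increment_id=str(row["increment_id"]),
                top_depth_cm=float(row["top_depth_cm"]),
                bottom_depth_cm=float(row["bottom_depth_cm"]),
                age_estimate=age_ce,
            )
        )

    counts: list[TaxonIncrementCount] = []
    for idx, row in counts_frame.iterrows():
        try:
            group = Group(str(row["group"]).strip().lower())
        except ValueError as exc:
            raise ValidationError(
                f"counts row {idx}: unknown group {row['group']!r}"
            ) from exc
        try:
            counts.append(
                TaxonIncrementCount(
                    core_id=str(row["core_id"]),
                    increment_id=str(row["increment_id"]),
                    taxon=str(row["taxon"]),
                    group=group,
                    is_predator=_parse_bool(row["is_predator"]),
                    n_articulated=int(row["n_articulated"]),
                    n_left=int(row["n_left"]),
                    n_right=int(row["n_right"]),
                    n_whole=int(row["n_whole"]),
                    n_drilled=int(row["n_drilled"]),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"counts row {idx}: {exc}") from exc
        except ValueError as exc:
            raise ValidationError(f"counts row {idx}: {exc}") from exc

    return CoreDataset(
        increments=increments, counts=counts, metadata=dict(metadata or {})
    )


def write_core_table(
    dataset: CoreDataset,
    counts_path: str | Path,
    increments_path: str | Path,
) -> None:
    """Write a dataset to the canonical counts/increments CSV pair.

    Ages are written in calendar years CE with ``age_convention=CE`` so
    that writer output read back and rewritten is byte-identical.
    """
    counts_frame = pd.DataFrame(
        [
            {
                "core_id": row.core_id,
                "increment_id": row.increment_id,
                "taxon": row.taxon,
                "group": row.group.value,
                "is_predator": row.is_predator,
                "n_articulated": row.n_articulated,
                "n_left": row.n_left,
                "n_right": row.n_right,
                "n_whole": row.n_whole,
                "n_drilled": row.n_drilled,
            }
            for row in dataset.counts
        ],
        columns=COUNT_COLUMNS,
    )
    increments_frame = pd.DataFrame(
        [
            {
                "core_id": inc.core_id,
                "increment_id": inc.increment_id,
                "top_depth_cm": inc.top_depth_cm,
                "bottom_depth_cm": inc.bottom_depth_cm,
                "age_estimate": inc.age_estimate,
                "age_convention": "CE",
            }
            for inc in dataset.increments
        ],
        columns=INCREMENT_COLUMNS,
    )
    counts_frame.to_csv(counts_path, index=False)
    increments_frame.to_csv(increments_path, index=False)


# ---------------------------------------------------------------------------
# Pooling and binning
# ---------------------------------------------------------------------------


def _depth_grid(dataset: CoreDataset) -> tuple[tuple[float, float], ...]:
    return tuple(
        (round(inc.top_depth_cm, 6), round(inc.bottom_depth_cm, 6))
        for inc in dataset.increments
    )


def pool_replicate_cores(
    datasets: Sequence[CoreDataset], pooled_core_id: str | None = None
) -> CoreDataset:
    """Sum counts across replicate cores sharing one depth grid.

    Replicate cores taken a few metres apart at the same station are
    pooled to increase sample size per increment.  Each input dataset
    must contain exactly one core and all cores must share an identical
    increment depth grid; counts are summed per (increment, taxon).
    """
    if not datasets:
        raise ValidationError("no datasets to pool")
    for ds in datasets:
        if len(ds.core_ids()) != 1:
            raise AlignmentError(
                "each replicate dataset must contain exactly one core"
            )
    reference = datasets[0]
    grid = _depth_grid(reference)
    for ds in datasets[1:]:
        if _depth_grid(ds) != grid:
            raise AlignmentError(
                f"depth grid of core {ds.core_ids()[0]!r} does not match "
                f"core {reference.core_ids()[0]!r}"
            )
    core_ids = [ds.core_ids()[0] for ds in datasets]
    new_core = pooled_core_id or "+".join(core_ids)

    # map each dataset's increments to the reference by depth interval
    ref_by_depth = {
        (round(inc.top_depth_cm, 6), round(inc.bottom_depth_cm, 6)): inc
        for inc in reference.increments
    }
    pooled: dict[tuple[str, str], dict] = {}
    for ds in datasets:
        inc_to_ref = {
            inc.increment_id: ref_by_depth[
                (round(inc.top_depth_cm, 6), round(inc.bottom_depth_cm, 6))
            ].increment_id
            for inc in ds.increments
        }
        for row in ds.counts:
            key = (inc_to_ref[row.increment_id], row.taxon)
            entry = pooled.setdefault(
                key,
                {
                    "group": row.group,
                    "is_predator": row.is_predator,
                    "n_articulated": 0,
                    "n_left": 0,
                    "n_right": 0,
                    "n_whole": 0,
                    "n_drilled": 0,
                },
            )
            if entry["group"] is not row.group or entry["is_predator"] != row.is_predator:
                raise ValidationError(
                    f"taxon {row.taxon!r} has inconsistent group/predator flags "
                    "across replicates"
                )
            for field in ("n_articulated", "n_left", "n_right", "n_whole", "n_drilled"):
                entry[field] += getattr(row, field)

    increments = [
        dataclasses.replace(inc, core_id=new_core) for inc in reference.increments
    ]
    counts = [
        TaxonIncrementCount(
            core_id=new_core,
            increment_id=increment_id,
            taxon=taxon,
            group=entry["group"],
            is_predator=entry["is_predator"],
            n_articulated=entry["n_articulated"],
            n_left=entry["n_left"],
            n_right=entry["n_right"],
            n_whole=entry["n_whole"],
            n_drilled=entry["n_drilled"],
        )
        for (increment_id, taxon), entry in sorted(pooled.items())
    ]
    metadata = dict(reference.metadata)
    metadata["pooled_from"] = core_ids
    return CoreDataset(increments=increments, counts=counts, metadata=metadata)


def pool_surface_increments(
    dataset: CoreDataset,
    boundary_cm: float = 20.0,
    allow_unpaired: bool = False,
) -> CoreDataset:
    """Merge adjacent pairs of thin increments above ``boundary_cm``.

    Cores are sliced more finely near the surface (2 cm vs 5 cm); the
    adjacent thin increments are pooled pairwise to increase sample size
    and match the resolution of the deeper slices.  Pairs are formed from
    the top down; with an odd number of increments above the boundary the
    deepest one is left unpaired only when ``allow_unpaired`` is set (a
    warning is logged), otherwise a :class:`PairingError` is raised.
    """
    new_increments: list[Increment] = []
    id_map: dict[tuple[str, str], str] = {}
    for core_id in dataset.core_ids():
        core_incs = [inc for inc in dataset.increments if inc.core_id == core_id]
        above = [inc for inc in core_incs if inc.bottom_depth_cm <= boundary_cm + _DEPTH_TOL]
        below = [inc for inc in core_incs if inc.bottom_depth_cm > boundary_cm + _DEPTH_TOL]
        for first, second in zip(above[0::2], above[1::2]):
            if abs(first.bottom_depth_cm - second.top_depth_cm) > _DEPTH_TOL:
                raise PairingError(
                    f"{core_id}: increments {first.increment_id} and "
                    f"{second.increment_id} are not adjacent"
                )
            ages = [
                inc.age_estimate
                for inc in (first, second)
                if inc.age_estimate is not None
            ]
            merged = Increment(
                core_id=core_id,
                increment_id=f"{first.increment_id}+{second.increment_id}",
                top_depth_cm=first.top_depth_cm,
                bottom_depth_cm=second.bottom_depth_cm,
                age_estimate=sum(ages) / len(ages) if ages else None,
            )
            new_increments.append(merged)
            id_map[(core_id, first.increment_id)] = merged.increment_id
            id_map[(core_id, second.increment_id)] = merged.increment_id
        if len(above) % 2 == 1:
            leftover = above[-1]
            if not allow_unpaired:
                raise PairingError(
                    f"{core_id}: odd number of increments above {boundary_cm} cm; "
                    f"{leftover.increment_id} cannot be paired "
                    "(pass allow_unpaired=True to keep it as-is)"
                )
            logger.warning(
                "%s: leaving surface increment %s unpaired",
                core_id,
                leftover.increment_id,
            )
            new_increments.append(leftover)
            id_map[(core_id, leftover.increment_id)] = leftover.increment_id
        for inc in below:
            new_increments.append(inc)
            id_map[(core_id, inc.increment_id)] = inc.increment_id

    pooled: dict[tuple[str, str, str], dict] = {}
    for row in dataset.counts:
        new_id = id_map[(row.core_id, row.increment_id)]
        key = (row.core_id, new_id, row.taxon)
        entry = pooled.setdefault(
            key,
            {
                "group": row.group,
                "is_predator": row.is_predator,
                "n_articulated": 0,
                "n_left": 0,
                "n_right": 0,
                "n_whole": 0,
                "n_drilled": 0,
            },
        )
        for field in ("n_articulated", "n_left", "n_right", "n_whole", "n_drilled"):
            entry[field] += getattr(row, field)
    counts = [
        TaxonIncrementCount(
            core_id=core_id,
            increment_id=increment_id,
            taxon=taxon,
            group=entry["group"],
            is_predator=entry["is_predator"],
            n_articulated=entry["n_articulated"],
            n_left=entry["n_left"],
            n_right=entry["n_right"],
            n_whole=entry["n_whole"],
            n_drilled=entry["n_drilled"],
        )
        for (core_id, increment_id, taxon), entry in sorted(pooled.items())
    ]
    return CoreDataset(
        increments=new_increments, counts=counts, metadata=dict(dataset.metadata)
    )


def assign_temporal_units(
    dataset: CoreDataset,
    boundaries: Sequence[float] = DEFAULT_UNIT_BOUNDARIES,
) -> CoreDataset:
    """Assign each increment to a temporal unit from its age estimate.

    ``boundaries`` are the three calendar-year cuts (CE) between the four
    units, oldest to youngest.  Ages below the first cut fall in the
    Holocene unit; ages at or above the last cut in the youngest unit.
    """
    b0, b1, b2 = (float(b) for b in boundaries)
    if not b0 < b1 < b2:
        raise ValidationError(f"unit boundaries must be increasing, got {boundaries}")
    missing = [
        inc.increment_id for inc in dataset.increments if inc.age_estimate is None
    ]
    if missing:
        raise ValidationError(
            "increments without age estimates: " + ", ".join(missing)
        )
    new_increments = []
    for inc in dataset.increments:
        age = inc.age_estimate
        if age < b0:
            unit = TemporalUnit.HOLOCENE
        elif age < b1:
            unit = TemporalUnit.C17_EARLY_C19
        elif age < b2:
            unit = TemporalUnit.LATE_C19_EARLY_C20
        else:
            unit = TemporalUnit.LATE_C20_C21
        new_increments.append(dataclasses.replace(inc, temporal_unit=unit))
    return CoreDataset(
        increments=new_increments,
        counts=list(dataset.counts),
        metadata=dict(dataset.metadata),
    )


def total_specimen_count(dataset: CoreDataset) -> int:
    """Total raw skeletal elements (valves + 2x articulated + whole shells).

    Conserved by both pooling operations; used by conservation checks.
    """
    total = 0
    for row in dataset.counts:
        total += row.n_left + row.n_right + 2 * row.n_articulated + row.n_whole
    return total
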