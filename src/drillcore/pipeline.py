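"""End-to-end orchestration of the drilling-predation analysis chain.

A :class:`RunConfig` (usually loaded from YAML) names either a built-in
synthetic scenario or a counts/increments CSV pair, and the pipeline
runs: read/simulate -> replicate pooling -> surface-increment pooling ->
temporal-unit assignment -> DF estimation -> predator-trend Monte Carlo
-> random-walk/breakpoint/rho tests -> species-level Fisher contrasts ->
community battery (NMDS, PERMANOVA, Kruskal-Wallis, dbRDA), writing CSV
tables, JSON test records and a run manifest.  Every random stage is
seeded from the single configured seed, so re-running a config
reproduces its outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core_model import (
    CoreDataset,
    DEFAULT_UNIT_BOUNDARIES,
    DrillcoreError,
    Group,
    ValidationError,
    assign_temporal_units,
    pool_replicate_cores,
    pool_surface_increments,
    read_core_table,
    write_core_table,
)
from .community_stats import (
    DissimilarityMatrix,
    bray_curtis,
    dbrda,
    df_by_unit_tests,
    nmds,
    permanova,
    sqrt_transform,
    to_proportions,
)
from .df_randomwalk import (
    DFSeries,
    breakpoint_significance,
    df_depth_rho_test,
    simulate_ensemble,
)
from .drilling_metrics import (
    assemblage_df_series,
    group_df_series,
    most_abundant_prey,
    prepost_fisher,
)
from .predator_trend import levels_from_dataset, predator_null_test
from .synthetic_core import make_scenario, simulate_study

logger = logging.getLogger(__name__)

ALL_STAGES = ("df", "predtrend", "dfwalk", "species", "community")


class PipelineError(DrillcoreError):
    """An analysis stage failed; the message names the stage."""


@dataclasses.dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: str
    scenario: str | None = None
    counts_path: str | None = None
    increments_path: str | None = None
    seed: int = 0
    min_n: int = 20
    n_iter_predator: int = 10_000
    n_iter_walk: int = 10_000
    n_perm_permanova: int = 999
    n_perm_dbrda: int = 999
    n_replicates: int = 2
    pool_surface: bool = True
    boundary_cm: float = 20.0
    unit_boundaries: tuple[float, float, float] = DEFAULT_UNIT_BOUNDARIES
    scenario_overrides: dict = dataclasses.field(default_factory=dict)
    #: temporal units excluded from the depth-ordered trend tests, e.g.
    #: detached Holocene samples whose depth is not an age proxy for the
    #: rest of the succession (cross-site concatenation is opt-in).
    #: None = auto: the po_like scenario excludes its detached Holocene
    #: tail; everything else excludes nothing.
    trend_exclude_units: tuple[str, ...] | None = None
    make_plots: bool = False

    def __post_init__(self) -> None:
        if self.scenario is None and (
            self.counts_path is None or self.increments_path is None
        ):
            raise ValidationError(
                "config must name a scenario or a counts/increments CSV pair"
            )
        for field in ("n_iter_predator", "n_iter_walk", "n_perm_permanova", "n_perm_dbrda"):
            if getattr(self, field) < 100:
                raise ValidationError(f"{field} must be at least 100")
        if not isinstance(self.seed, int):
            raise ValidationError("seed must be an explicit integer")
        self.unit_boundaries = tuple(float(b) for b in self.unit_boundaries)
        if self.trend_exclude_units is None:
            self.trend_exclude_units = (
                ("holocene",) if self.scenario == "po_like" else ()
            )
        else:
            self.trend_exclude_units = tuple(str(u) for u in self.trend_exclude_units)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["unit_boundaries"] = list(self.unit_boundaries)
        out["trend_exclude_units"] = list(self.trend_exclude_units or ())
        return out

    def analysis_dict(self) -> dict:
        """The configuration fields that determine the results (the
        output location is not one of them)."""
        out = self.to_dict()
        out.pop("out_dir")
        return out

    def config_hash(self) -> str:
        payload = yaml.safe_dump(self.analysis_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _json_dump(obj, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, sort_keys=True, indent=2)
        fh.write("\n")


def _stage(name: str):
    def decorator(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except DrillcoreError as exc:
                raise PipelineError(f"[{name}] {exc}") from exc

        return wrapped

    return decorator


@_stage("data")
def _acquire_data(config: RunConfig, seeds: dict, out: Path) -> CoreDataset:
    if config.scenario is not None:
        scenario = make_scenario(config.scenario, **config.scenario_overrides)
        scenario = dataclasses.replace(
            scenario, unit_boundaries=config.unit_boundaries
        )
        logger.info(
            "simulating scenario %s (%d replicates, seed %d)",
            config.scenario,
            config.n_replicates,
            seeds["simulate"],
        )
        replicates = simulate_study(
            scenario, n_replicates=config.n_replicates, seed=seeds["simulate"]
        )[scenario.name]
        write_core_table(
            replicates[0], out / "simulated_counts_r1.csv", out / "simulated_increments_r1.csv"
        )
        dataset = pool_replicate_cores(replicates)
    else:
        logger.info("reading %s / %s", config.counts_path, config.increments_path)
        for path in (config.counts_path, config.increments_path):
            if not Path(path).is_file():
                raise ValidationError(f"input file not found: {path}")
        dataset = read_core_table(config.counts_path, config.increments_path)
    if config.pool_surface:
        dataset = pool_surface_increments(
            dataset, boundary_cm=config.boundary_cm, allow_unpaired=True
        )
    dataset = assign_temporal_units(dataset, config.unit_boundaries)
    write_core_table(dataset, out / "analysis_counts.csv", out / "analysis_increments.csv")
    return dataset


@_stage("df")
def _stage_df(config: RunConfig, dataset: CoreDataset, out: Path) -> dict:
    estimates = {"assemblage": assemblage_df_series(dataset, min_n=config.min_n)}
    for group in (Group.BIVALVE, Group.GASTROPOD):
        estimates[group.value + "s"] = group_df_series(dataset, group, min_n=config.min_n)
    rows = []
    for scope, series in estimates.items():
        for est in series:
            rows.append(
                {
                    "core_id": est.core_id,
                    "increment_id": est.increment_id,
                    "scope": est.scope,
                    "n_individuals": est.n_individuals,
                    "n_drilled": est.n_drilled,
                    "df": est.df,
                    "included": est.included,
                }
            )
    pd.DataFrame(rows).to_csv(out / "df_estimates.csv", index=False)
    return estimates


def _trend_dataset(config: RunConfig, dataset: CoreDataset) -> CoreDataset:
    """Restrict to increments whose depth order is an age proxy."""
    if not config.trend_exclude_units:
        return dataset
    excluded = set(config.trend_exclude_units)
    keep = [
        inc
        for inc in dataset.increments
        if inc.temporal_unit is None or inc.temporal_unit.value not in excluded
    ]
    keys = {(inc.core_id, inc.increment_id) for inc in keep}
    counts = [row for row in dataset.counts if (row.core_id, row.increment_id) in keys]
    return CoreDataset(increments=keep, counts=counts, metadata=dict(dataset.metadata))


@_stage("predtrend")
def _stage_predtrend(config: RunConfig, dataset: CoreDataset, seeds: dict, out: Path) -> dict:
    levels = levels_from_dataset(_trend_dataset(config, dataset))
    result = predator_null_test(
        levels, n_iter=config.n_iter_predator, seed=seeds["predator"]
    )
    record = result.to_dict()
    _json_dump(record, out / "predator_trend.json")
    pd.DataFrame({"null_rho": result.null_rhos}).to_csv(
        out / "predator_null_rhos.csv", index=False
    )
    return record


@_stage("dfwalk")
def _stage_dfwalk(config: RunConfig, dataset: CoreDataset, estimates: dict, seeds: dict, out: Path) -> dict:
    trend_data = _trend_dataset(config, dataset)
    keys = {(inc.core_id, inc.increment_id) for inc in trend_data.increments}
    kept = [e for e in estimates["assemblage"] if (e.core_id, e.increment_id) in keys]
    series = DFSeries.from_estimates(kept, trend_data)
    ensemble = simulate_ensemble(
        series, n_iter=config.n_iter_walk, seed=seeds["walk"]
    )
    record: dict = {"n_levels": series.n_levels, "n_iter": config.n_iter_walk, "seed": seeds["walk"]}
    if series.n_levels >= 6:
        breakpoint = breakpoint_significance(series, ensemble)
        record["breakpoint"] = breakpoint.to_dict()
    else:
        record["breakpoint"] = None
        logger.warning("too few levels for breakpoint analysis")
    rho = df_depth_rho_test(series, ensemble)
    record["rho_test"] = rho.to_dict() if rho is not None else None
    _json_dump(record, out / "df_walk.json")
    pd.DataFrame(
        {
            "increment_id": series.increment_ids,
            "mid_depth_cm": series.depths,
            "df": series.values,
            "band_lower": ensemble.band_lower,
            "band_upper": ensemble.band_upper,
        }
    ).to_csv(out / "df_walk_bands.csv", index=False)
    return record


@_stage("species")
def _stage_species(config: RunConfig, dataset: CoreDataset, out: Path) -> list:
    rows = []
    for taxon in most_abundant_prey(dataset, k=4):
        contrast = prepost_fisher(dataset, taxon)
        if contrast is None:
            rows.append({"taxon": taxon, "defined": False})
            continue
        rows.append(
            {
                "taxon": taxon,
                "defined": True,
                "pre_drilled": contrast.pre_drilled,
                "pre_undrilled": contrast.pre_undrilled,
                "post_drilled": contrast.post_drilled,
                "post_undrilled": contrast.post_undrilled,
                "odds_ratio": contrast.odds_ratio,
                "p": contrast.p_two_sided,
            }
        )
    pd.DataFrame(rows).to_csv(out / "species_contrasts.csv", index=False)
    return rows


@_stage("community")
def _stage_community(config: RunConfig, dataset: CoreDataset, estimates: dict, seeds: dict, out: Path) -> dict:
    matrix = to_proportions(dataset, min_n=config.min_n)
    transformed = sqrt_transform(matrix)
    dissim = bray_curtis(transformed)
    record: dict = {}

    ordination = nmds(dissim, k=2, seed=seeds["nmds"])
    record["nmds"] = {
        "stress": ordination.stress,
        "converged": ordination.converged,
        "n_restarts": ordination.n_restarts,
    }

    increment_map = {inc.increment_id: inc for inc in dataset.increments}
    units = [increment_map[sid].temporal_unit.value for sid in dissim.ids]
    unit_counts = pd.Series(units).value_counts()
    usable = unit_counts[unit_counts >= 2]
    if usable.size >= 2:
        keep = [i for i, u in enumerate(units) if u in usable.index]
        sub_dissim = DissimilarityMatrix(
            ids=tuple(dissim.ids[i] for i in keep),
            values=dissim.values[np.ix_(keep, keep)],
        )
        perm = permanova(
            sub_dissim,
            [units[i] for i in keep],
            n_perm=config.n_perm_permanova,
            seed=seeds["permanova"],
            factor="temporal_unit",
        )
        record["permanova"] = perm.to_dict()
    else:
        record["permanova"] = None
        logger.warning("too few temporal units with >= 2 samples for PERMANOVA")

    df_by_unit: dict[str, list[float]] = {}
    for est in estimates["assemblage"]:
        if not est.included or est.df is None:
            continue
        unit = increment_map[est.increment_id].temporal_unit
        df_by_unit.setdefault(unit.value, []).append(est.df)
    try:
        battery = df_by_unit_tests(df_by_unit)
        record["df_by_unit"] = battery.to_dict()
    except DrillcoreError as exc:
        record["df_by_unit"] = None
        logger.warning("DF-by-unit battery skipped: %s", exc)

    df_by_increment = {
        est.increment_id: est.df
        for est in estimates["assemblage"]
        if est.included and est.df is not None
    }
    keep = [i for i, sid in enumerate(dissim.ids) if sid in df_by_increment]
    if len(keep) >= 4:
        sub_dissim = DissimilarityMatrix(
            ids=tuple(dissim.ids[i] for i in keep),
            values=dissim.values[np.ix_(keep, keep)],
        )
        constraint = [df_by_increment[sub_dissim.ids[j]] for j in range(len(keep))]
        rda = dbrda(
            sub_dissim,
            constraint,
            n_perm=config.n_perm_dbrda,
            seed=seeds["dbrda"],
        )
        record["dbrda"] = rda.to_dict()
    else:
        record["dbrda"] = None
        logger.warning("too few samples with included DF for dbRDA")

    _json_dump(record, out / "community_tests.json")
    table = ordination.coordinates.copy()
    table.insert(0, "sample", table.index)
    table["df"] = [df_by_increment.get(sid) for sid in table.index]
    table["temporal_unit"] = units
    table.to_csv(out / "ordination.csv", index=False)
    return record


def _spawn_seeds(seed: int) -> dict[str, int]:
    root = np.random.SeedSequence(seed)
    names = ("simulate", "predator", "walk", "nmds", "permanova", "dbrda")
    children = root.spawn(len(names))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(names, children)
    }


def run_pipeline(config: RunConfig, stages: tuple[str, ...] = ALL_STAGES) -> dict:
    """Run the configured analysis chain and write all outputs.

    Returns the result bundle (also written to ``summary.json``); raises
    :class:`PipelineError` with the failing stage's name on error.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _spawn_seeds(config.seed)
    dataset = _acquire_data(config, seeds, out)
    results: dict = {}

    estimates = _stage_df(config, dataset, out)
    if "predtrend" in stages:
        results["predator_trend"] = _stage_predtrend(config, dataset, seeds, out)
    if "dfwalk" in stages:
        results["df_walk"] = _stage_dfwalk(config, dataset, estimates, seeds, out)
    if "species" in stages:
        results["species"] = _stage_species(config, dataset, out)
    if "community" in stages:
        results["community"] = _stage_community(config, dataset, estimates, seeds, out)

    if config.make_plots:
        from . import plotting

        series_record = results.get("df_walk")
        if series_record is not None:
            series = DFSeries.from_estimates(estimates["assemblage"], dataset)
            bands = pd.read_csv(out / "df_walk_bands.csv")
            plotting.save_df_profile(
                series,
                bands["band_lower"].to_numpy(),
                bands["band_upper"].to_numpy(),
                out / "df_profile.png",
            )

    manifest = {
        "config": config.analysis_dict(),
        "config_hash": config.config_hash(),
        "seeds": seeds,
        "version": __version__,
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    _json_dump(manifest, out / "manifest.json")
    _json_dump(results, out / "summary.json")
    return results
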