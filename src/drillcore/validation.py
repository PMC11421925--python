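"""Simulation experiments validating the estimators and tests.

Each function runs a self-contained, seeded experiment — estimator
recovery, type-I error calibration, power, parameter recovery, or
end-to-end scenario detection — and returns plain numbers.  They back
both the acceptance checks of the test suite and the reproducibility
script, so the reported operating characteristics are always recomputed
from scratch rather than quoted.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .core_model import Group
from .df_randomwalk import (
    DFSeries,
    breakpoint_significance,
    df_depth_rho_test,
    simulate_ensemble,
)
from .drilling_metrics import assemblage_df_series
from .predator_trend import LevelAbundance, predator_null_test
from .community_stats import (
    DissimilarityMatrix,
    dbrda,
    permanova,
)
from .pipeline import RunConfig, run_pipeline
from .synthetic_core import ScenarioConfig, TaxonSpec, simulate_core


def _child_seeds(seed: int, n: int) -> list[int]:
    return [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(seed).spawn(n)
    ]


def _uniform_config(p_drill, articulation=1.0, retention=1.0,
                    n_increments=10, mean=200.0) -> ScenarioConfig:
    taxa = (
        TaxonSpec(
            name="clam",
            group=Group.BIVALVE,
            abundance=(0.5,) * 4,
            drilling=(p_drill,) * 4,
            articulation_p=articulation,
            retention_p=retention,
        ),
        TaxonSpec(
            name="snail",
            group=Group.GASTROPOD,
            abundance=(0.5,) * 4,
            drilling=(p_drill,) * 4,
        ),
    )
    return ScenarioConfig(
        name="uniform",
        taxa=taxa,
        n_increments=n_increments,
        surface_slices=False,
        sample_size_mean=mean,
        time_averaging_sd_yr=0.0,
    )


def df_recovery(p: float, n_cores: int = 50, seed: int = 0,
                articulation: float = 1.0, retention: float = 1.0) -> dict:
    """Mean assemblage DF over seeded cores vs the true drilling rate."""
    config = _uniform_config(p, articulation=articulation, retention=retention)
    means = []
    for core_seed in _child_seeds(seed, n_cores):
        ds = simulate_core(config, seed=core_seed)
        vals = [e.df for e in assemblage_df_series(ds) if e.included]
        means.append(float(np.mean(vals)))
    mean = float(np.mean(means))
    se = float(np.std(means, ddof=1) / math.sqrt(len(means)))
    return {"true_p": p, "mean_df": mean, "bias": mean - p, "se": se,
            "n_cores": n_cores}


def predator_trend_type1(n_datasets: int = 500, n_levels: int = 20,
                         n_per_level: int = 200, p: float = 0.01,
                         n_iter: int = 1_000, alpha: float = 0.05,
                         seed: int = 0) -> dict:
    """Rejection rate of the predator-trend test under its own null."""
    rejections = 0
    rng = np.random.default_rng(seed)
    test_seeds = _child_seeds(seed + 1, n_datasets)
    depths = 5.0 * np.arange(1, n_levels + 1)
    for i in range(n_datasets):
        counts = rng.binomial(n_per_level, p, size=n_levels)
        if counts.sum() in (0, n_levels * n_per_level):
            continue
        levels = [
            LevelAbundance(f"l{j}", depths[j], n_per_level, int(counts[j]))
            for j in range(n_levels)
        ]
        try:
            result = predator_null_test(levels, n_iter=n_iter, seed=test_seeds[i])
        except Exception:
            continue
        rejections += result.p_two_tailed < alpha
    return {"rate": rejections / n_datasets, "n": n_datasets}


def predator_trend_power(n_datasets: int = 100, n_levels: int = 20,
                         n_per_level: int = 200, p_base: float = 0.04,
                         n_iter: int = 1_000, seed: int = 0) -> dict:
    """Power against a linear decline from ``p_base`` at depth to 0 at top."""
    detections = 0
    rng = np.random.default_rng(seed)
    test_seeds = _child_seeds(seed + 1, n_datasets)
    depths = 5.0 * np.arange(1, n_levels + 1)
    probs = p_base * np.arange(n_levels) / (n_levels - 1)  # top-first 0 .. p_base
    for i in range(n_datasets):
        counts = rng.binomial(n_per_level, probs)
        levels = [
            LevelAbundance(f"l{j}", depths[j], n_per_level, int(counts[j]))
            for j in range(n_levels)
        ]
        result = predator_null_test(levels, n_iter=n_iter, seed=test_seeds[i])
        detections += result.p_two_tailed < 0.05 and result.rho_observed > 0
    return {"rate": detections / n_datasets, "n": n_datasets}


def _step_series(rng: np.random.Generator, n_levels: int = 20,
                 high: float = 0.25, drop: float = 0.15,
                 noise_sd: float = 0.02) -> DFSeries:
    half = n_levels // 2
    vals = np.concatenate([
        rng.normal(high, noise_sd, half),
        rng.normal(high - drop, noise_sd, n_levels - half),
    ])
    return DFSeries(
        tuple(f"i{k}" for k in range(n_levels)),
        5.0 * np.arange(n_levels, 0, -1),
        np.clip(vals, 0.0, None),
    )


def breakpoint_recovery(n_datasets: int = 100, n_iter: int = 1_000,
                        seed: int = 0) -> dict:
    """Detection of a 0.15 DF step at a known level under walk-null testing."""
    rng = np.random.default_rng(seed)
    ens_seeds = _child_seeds(seed + 1, n_datasets)
    hits = 0
    for i in range(n_datasets):
        series = _step_series(rng)
        ensemble = simulate_ensemble(series, n_iter=n_iter, seed=ens_seeds[i])
        result = breakpoint_significance(series, ensemble)
        hits += result.significant_05 and abs(result.boundary_index - 10) <= 1
    return {"rate": hits / n_datasets, "n": n_datasets}


def walk_null_self_consistency(n_datasets: int = 100, n_iter: int = 1_000,
                               seed: int = 0) -> dict:
    """False-positive rate when the data themselves are walk-null draws.

    A parent series defines a difference pool; each dataset is one
    random-walk realisation from it, then tested against an ensemble
    built from its own differences.
    """
    rng = np.random.default_rng(seed)
    parent_vals = np.clip(rng.normal(0.2, 0.02, 20), 0.0, None)
    parent = DFSeries(
        tuple(f"i{k}" for k in range(20)), 5.0 * np.arange(20, 0, -1), parent_vals
    )
    draws = simulate_ensemble(parent, n_iter=n_datasets, seed=seed + 7)
    ens_seeds = _child_seeds(seed + 1, n_datasets)
    false_positives = 0
    for i in range(n_datasets):
        series = DFSeries(parent.increment_ids, parent.depths,
                          draws.series_matrix[i])
        ensemble = simulate_ensemble(series, n_iter=n_iter, seed=ens_seeds[i])
        result = breakpoint_significance(series, ensemble)
        false_positives += result.significant_05
    return {"rate": false_positives / n_datasets, "n": n_datasets}


def df_rho_type1(n_datasets: int = 200, n_iter: int = 1_000, seed: int = 0) -> dict:
    """Type-I error of the depth-DF rho test on ensemble-generated data.

    Data series are independent walk realisations from a parent series'
    difference pool, tested against the method's null ensemble for that
    parent; by exchangeability of the draws the nominal rate holds.
    """
    rng = np.random.default_rng(seed)
    parent_vals = np.clip(rng.normal(0.2, 0.02, 20), 0.0, None)
    parent = DFSeries(
        tuple(f"i{k}" for k in range(20)), 5.0 * np.arange(20, 0, -1), parent_vals
    )
    null_ensemble = simulate_ensemble(parent, n_iter=n_iter, seed=seed + 3)
    draws = simulate_ensemble(parent, n_iter=n_datasets, seed=seed + 11)
    rejections = 0
    usable = 0
    for i in range(n_datasets):
        series = DFSeries(parent.increment_ids, parent.depths,
                          draws.series_matrix[i])
        result = df_depth_rho_test(series, null_ensemble)
        if result is None:
            continue
        usable += 1
        rejections += result.p_two_tailed < 0.05
    return {"rate": rejections / max(usable, 1), "n": usable}


def _random_dissim(rng: np.random.Generator, n: int) -> DissimilarityMatrix:
    pts = rng.normal(size=(n, 3))
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    return DissimilarityMatrix(ids=tuple(f"s{i}" for i in range(n)), values=d)


def permanova_type1(n_datasets: int = 500, n: int = 20, n_perm: int = 199,
                    seed: int = 0) -> dict:
    """Type-I error of PERMANOVA under random label assignment."""
    rng = np.random.default_rng(seed)
    d = _random_dissim(rng, n)
    perm_seeds = _child_seeds(seed + 1, n_datasets)
    labels = np.array(["a"] * (n // 2) + ["b"] * (n - n // 2))
    rejections = 0
    p_values = []
    for i in range(n_datasets):
        shuffled = labels[rng.permutation(n)]
        result = permanova(d, shuffled, n_perm=n_perm, seed=perm_seeds[i])
        p_values.append(result.p_perm)
        rejections += result.p_perm < 0.05
    return {"rate": rejections / n_datasets, "n": n_datasets,
            "p_values": p_values}


def dbrda_type1(n_datasets: int = 500, n: int = 20, n_perm: int = 199,
                seed: int = 0) -> dict:
    """Type-I error of dbRDA with a permuted (unrelated) constraint."""
    rng = np.random.default_rng(seed)
    d = _random_dissim(rng, n)
    x = rng.normal(size=n)
    perm_seeds = _child_seeds(seed + 1, n_datasets)
    rejections = 0
    p_values = []
    for i in range(n_datasets):
        result = dbrda(d, x[rng.permutation(n)], n_perm=n_perm, seed=perm_seeds[i])
        p_values.append(result.p_perm)
        rejections += result.p_perm < 0.05
    return {"rate": rejections / n_datasets, "n": n_datasets,
            "p_values": p_values}


@dataclasses.dataclass
class ScenarioDetection:
    df_decline_rate: float
    predator_decline_rate: float
    any_alarm_rate_01: float
    n_seeds: int


def scenario_detection(scenario: str, n_seeds: int = 20, out_root=None,
                       seed: int = 0, n_iter: int = 1_000) -> ScenarioDetection:
    """Run the full pipeline over seeds and summarise what it reports.

    "DF decline" counts runs where either the breakpoint test or the
    depth-DF rho test is significant at 0.05 with the sign of an upward
    decrease; "predator decline" likewise for the predator trend test;
    the alarm rate counts runs with any of the three significant at
    0.01 (used for the null scenario).
    """
    import tempfile
    from pathlib import Path

    df_hits = pred_hits = alarms = 0
    run_seeds = _child_seeds(seed, n_seeds)
    with tempfile.TemporaryDirectory() as tmp:
        root = Path(out_root) if out_root is not None else Path(tmp)
        for i, run_seed in enumerate(run_seeds):
            config = RunConfig(
                out_dir=str(root / f"{scenario}-{i}"),
                scenario=scenario,
                seed=run_seed,
                n_iter_predator=n_iter,
                n_iter_walk=n_iter,
                n_perm_permanova=199,
                n_perm_dbrda=199,
            )
            results = run_pipeline(config)
            bp = results["df_walk"]["breakpoint"]
            rho = results["df_walk"]["rho_test"]
            pred = results["predator_trend"]
            df_sig = bool(
                (bp and bp["significant_05"] and bp["t_observed"] > 0)
                or (rho and rho["p_two_tailed"] < 0.05 and rho["rho_observed"] > 0)
            )
            pred_sig = pred["p_two_tailed"] < 0.05 and pred["rho_observed"] > 0
            alarm = bool(
                (bp and bp["p"] < 0.01)
                or (rho and rho["p_two_tailed"] < 0.01)
                or pred["p_two_tailed"] < 0.01
            )
            df_hits += df_sig
            pred_hits += pred_sig
            alarms += alarm
    return ScenarioDetection(
        df_decline_rate=df_hits / n_seeds,
        predator_decline_rate=pred_hits / n_seeds,
        any_alarm_rate_01=alarms / n_seeds,
        n_seeds=n_seeds,
    )
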