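"""First-difference bootstrap walks, breakpoint search, and trend tests."""

from __future__ import annotations

import math
import statistics

import numpy as np
import pytest

from drillcore import (
    DFSeries,
    ValidationError,
    breakpoint_significance,
    df_depth_rho_test,
    first_differences,
    max_t_breakpoint,
    moving_average,
    simulate_ensemble,
)


def series(values, depths=None):
    values = np.asarray(values, dtype=float)
    n = values.size
    depths = np.asarray(depths, float) if depths is not None else np.arange(n, 0, -1.0) * 5
    return DFSeries(tuple(f"i{k}" for k in range(n)), depths, values)


class TestFirstDifferences:
    def test_base_to_top_subtraction(self):
        assert first_differences(series([0.3, 0.2, 0.25])) == pytest.approx([-0.1, 0.05])

    def test_constant_series_zero_pool(self):
        assert np.all(first_differences(series([0.2] * 5)) == 0.0)

    def test_single_level_rejected(self):
        with pytest.raises(ValidationError):
            first_differences(series([0.2]))


class TestEnsemble:
    def test_constant_series_degenerates_to_start(self):
        ens = simulate_ensemble(series([0.2] * 6), n_iter=200, seed=0)
        assert np.all(ens.series_matrix == 0.2)
        assert np.all(ens.band_lower == 0.2) and np.all(ens.band_upper == 0.2)

    def test_reflection_keeps_walks_non_negative(self):
        ens = simulate_ensemble(series([0.0, 0.1, 0.2, 0.1, 0.0, 0.1]), n_iter=500, seed=1)
        assert np.all(ens.series_matrix >= 0)

    def test_reflection_from_zero(self):
        """Start 0 with pool {-0.1, +0.1}: every first step lands on +0.1
        (a drawn -0.1 is reflected), and no walk ever goes negative."""
        s = series([0.0, 0.1, 0.0])
        ens = simulate_ensemble(s, n_iter=200, seed=2)
        assert np.all(ens.series_matrix[:, 0] == 0.0)
        assert np.all(ens.series_matrix[:, 1] == pytest.approx(0.1))
        assert set(np.round(ens.series_matrix[:, 2], 10)) <= {0.0, 0.2}

    def test_first_column_is_start_value(self):
        s = series([0.31, 0.25, 0.28, 0.22, 0.18])
        ens = simulate_ensemble(s, n_iter=100, seed=3)
        assert np.all(ens.series_matrix[:, 0] == 0.31)

    def test_bit_reproducible(self):
        s = series([0.3, 0.25, 0.28, 0.2, 0.18, 0.1])
        a = simulate_ensemble(s, n_iter=300, seed=42)
        b = simulate_ensemble(s, n_iter=300, seed=42)
        assert np.array_equal(a.series_matrix, b.series_matrix)

    def test_mean_matches_brute_force_reflected_walk(self):
        """Per-level ensemble means agree with an independently coded
        scalar reflected-walk simulator (pool +-0.05, start 0.5)."""
        n_levels = 20
        # a 20-level series whose first-difference pool is {-0.05, +0.05}
        s20 = DFSeries(
            tuple(f"i{k}" for k in range(n_levels)),
            np.arange(n_levels, 0, -1.0),
            np.array([0.5, 0.45] * (n_levels // 2)),
        )
        assert set(np.round(first_differences(s20), 10)) == {-0.05, 0.05}
        pool = first_differences(s20)
        ens = simulate_ensemble(s20, n_iter=20_000, seed=7)

        import random

        rnd = random.Random(123)
        pool_list = list(pool)
        sums = [0.0] * n_levels
        sums2 = [0.0] * n_levels
        n_walks = 50_000
        for _ in range(n_walks):
            x = 0.5
            sums[0] += x
            sums2[0] += x * x
            for j in range(1, n_levels):
                d = rnd.choice(pool_list)
                nxt = x + d
                if nxt < 0:
                    nxt = x - d
                x = nxt
                sums[j] += x
                sums2[j] += x * x
        oracle_mean = np.array(sums) / n_walks
        oracle_var = np.array(sums2) / n_walks - oracle_mean**2
        lib_mean = ens.series_matrix.mean(axis=0)
        lib_var = ens.series_matrix.var(axis=0)
        se = np.sqrt(oracle_var / n_walks + lib_var / ens.n_iter)
        assert np.all(np.abs(lib_mean - oracle_mean) <= 3 * se + 1e-12)

    def test_lag1_autocorrelation_non_negative(self):
        """Walks built from a zero-mean pool are positively autocorrelated."""
        s = series([0.2, 0.25, 0.2, 0.15, 0.2, 0.25, 0.2])
        ens = simulate_ensemble(s, n_iter=2_000, seed=5)
        X = ens.series_matrix
        a, b = X[:, :-1].ravel(), X[:, 1:].ravel()
        r = np.corrcoef(a, b)[0, 1]
        assert r > 0

    def test_clamp_rule_and_random_start_similar_conclusions(self):
        rng = np.random.default_rng(6)
        vals = np.concatenate([rng.normal(0.25, 0.02, 8), rng.normal(0.1, 0.02, 8)])
        s = series(np.clip(vals, 0, None))
        base = breakpoint_significance(s, simulate_ensemble(s, 2_000, seed=1))
        clamp = breakpoint_significance(
            s, simulate_ensemble(s, 2_000, seed=1, negative_rule="clamp")
        )
        rand = breakpoint_significance(
            s, simulate_ensemble(s, 2_000, seed=1, random_start=True)
        )
        assert abs(base.p - clamp.p) < 0.1
        assert abs(base.p - rand.p) < 0.1


def brute_force_max_t(values, min_group=3):
    """Independent exhaustive split search using statistics stdlib."""
    n = len(values)
    best = None
    for b in range(min_group, n - min_group + 1):
        lower, upper = values[:b], values[b:]
        m1, m2 = statistics.fmean(lower), statistics.fmean(upper)
        ss1 = sum((x - m1) ** 2 for x in lower)
        ss2 = sum((x - m2) ** 2 for x in upper)
        pooled = (ss1 + ss2) / (n - 2)
        se = math.sqrt(pooled * (1 / b + 1 / (n - b)))
        t = (m1 - m2) / se if se > 0 else 0.0
        if best is None or abs(t) > abs(best[1]) + 1e-12:
            best = (b, t)
    return best


class TestMaxTBreakpoint:
    def test_pure_step_series_boundary(self):
        # noise-free groups have zero pooled variance, hence t = 0 by
        # convention; with six levels the only admissible split is b = 3
        scan = max_t_breakpoint(series([0.3, 0.3, 0.3, 0.1, 0.1, 0.1]))
        assert scan.boundary_index == 3
        assert scan.t_observed == 0.0

    def test_noisy_step_series_boundary(self):
        vals = [0.31, 0.29, 0.30, 0.32, 0.11, 0.09, 0.10, 0.12]
        scan = max_t_breakpoint(series(vals))
        assert scan.boundary_index == 4
        assert scan.t_observed > 0

    def test_constant_series_zero_t_tied(self):
        scan = max_t_breakpoint(series([0.2] * 8))
        assert scan.t_observed == 0.0
        assert scan.tied
        assert scan.boundary_index == 3  # first admissible boundary

    def test_mirror_symmetry(self):
        vals = [0.3, 0.28, 0.33, 0.12, 0.1, 0.09, 0.11, 0.1]
        fwd = max_t_breakpoint(series(vals))
        rev = max_t_breakpoint(series(vals[::-1]))
        assert fwd.t_observed == pytest.approx(-rev.t_observed)
        assert fwd.boundary_index == len(vals) - rev.boundary_index

    def test_agrees_with_brute_force_up_to_length_12(self):
        rng = np.random.default_rng(17)
        for n in range(6, 13):
            for _ in range(20):
                vals = np.abs(rng.normal(0.2, 0.08, n))
                scan = max_t_breakpoint(series(vals))
                b, t = brute_force_max_t(list(vals))
                assert scan.boundary_index == b
                assert scan.t_observed == pytest.approx(t, rel=1e-9)

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            max_t_breakpoint(series([0.1, 0.2, 0.3, 0.4, 0.5]))


class TestBreakpointSignificance:
    def test_bit_reproducible(self):
        rng = np.random.default_rng(2)
        vals = np.clip(np.concatenate(
            [rng.normal(0.25, 0.02, 10), rng.normal(0.1, 0.02, 10)]
        ), 0, None)
        s = series(vals)
        a = breakpoint_significance(s, simulate_ensemble(s, 1_000, seed=8))
        b = breakpoint_significance(s, simulate_ensemble(s, 1_000, seed=8))
        assert a.p == b.p and a.t_observed == b.t_observed
        assert np.array_equal(a.null_max_t, b.null_max_t)

    def test_step_detected(self):
        rng = np.random.default_rng(3)
        vals = np.clip(np.concatenate(
            [rng.normal(0.3, 0.02, 10), rng.normal(0.12, 0.02, 10)]
        ), 0, None)
        s = series(vals)
        result = breakpoint_significance(s, simulate_ensemble(s, 2_000, seed=9))
        assert result.significant_05
        assert abs(result.boundary_index - 10) <= 1
        assert result.boundary_depth_cm == pytest.approx(
            0.5 * (s.depths[result.boundary_index - 1] + s.depths[result.boundary_index])
        )


class TestRhoTest:
    def test_monotone_decline_gives_rho_one(self):
        s = series(np.linspace(0.3, 0.05, 10))
        ens = simulate_ensemble(s, 500, seed=0)
        result = df_depth_rho_test(s, ens)
        assert result.rho_observed == pytest.approx(1.0)

    def test_constant_series_missing(self):
        s = series([0.2] * 6)
        ens = simulate_ensemble(s, 100, seed=0)
        assert df_depth_rho_test(s, ens) is None

    def test_type1_error_on_walk_null_data(self):
        """Data drawn from the walk null are rejected at roughly the
        nominal rate (the autocorrelated null makes the band wide)."""
        from drillcore.validation import df_rho_type1

        result = df_rho_type1(n_datasets=200, n_iter=1_000, seed=31)
        assert 0.02 <= result["rate"] <= 0.08, result


def test_moving_average_five_level_means():
    vals = np.arange(10, dtype=float)
    out = moving_average(vals, 5)
    assert out == pytest.approx(np.arange(2.0, 8.0))
    with pytest.raises(ValidationError):
        moving_average(vals, 11)
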