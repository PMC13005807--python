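import math

import numpy as np
import pandas as pd
import pytest

from gridepi import scan as gscan
from gridepi.exceptions import (
    ConfigurationError,
    DataIntegrityError,
    InvalidExpectationError,
    NoCasesError,
)

from conftest import make_grid


# ---------------------------------------------------------------------------
# Independent brute-force oracle (deliberately separate from gridepi.scan)
# ---------------------------------------------------------------------------


def brute_force_best(grid, counts, cfg):
    """Exhaustively maximise the LLR over all distance-feasible windows.

    Builds each window as an explicit member set via per-centre
    (distance, id)-sorted growth with the stop-before-violation rule,
    and evaluates the LLR with plain math.log. Tie-break: smaller
    radius, then lower centre cell id.
    """
    ids = grid["cell_id"].to_numpy()
    x = grid["x"].to_numpy(float)
    y = grid["y"].to_numpy(float)
    pop = grid["population"].to_numpy(float)
    P = pop.sum()
    cvec = np.array([counts.get(int(i), 0) for i in ids], float)
    C = cvec.sum()
    best = None  # (llr, radius, centre_id, frozenset members)
    for i in range(len(ids)):
        dist = np.hypot(x - x[i], y - y[i])
        order = sorted(range(len(ids)), key=lambda j: (dist[j], ids[j]))
        members, wpop, wc = [], 0.0, 0.0
        for j in order:
            if members:  # growth constraints never remove the singleton
                if wpop + pop[j] > cfg.max_pop_fraction * P or dist[j] > cfg.max_radius_m:
                    break
            members.append(j)
            wpop += pop[j]
            wc += cvec[j]
            E = C * wpop / P
            ok = wc > E if cfg.direction == "high" else wc < E
            if ok:
                t1 = wc * math.log(wc / E) if wc > 0 else 0.0
                t2 = (C - wc) * math.log((C - wc) / (C - E)) if wc < C else 0.0
                llr = t1 + t2
            else:
                llr = 0.0
            key = (-llr, dist[j], ids[i])
            if best is None or key < best[0]:
                best = (key, frozenset(int(ids[m]) for m in members), llr)
    return best[1], best[2]


def random_small_grid(rng, n_max=25):
    n = int(rng.integers(4, n_max + 1))
    side = int(np.ceil(np.sqrt(n)))
    cells = rng.choice(side * side, size=n, replace=False)
    grid = make_grid(
        x=(cells % side + 0.5) * 1000.0,
        y=(cells // side + 0.5) * 1000.0,
        population=rng.integers(1, 200, size=n),
    )
    C = int(rng.integers(1, 80))
    counts_arr = rng.multinomial(C, np.ones(n) / n)
    counts = {int(cid): int(c) for cid, c in zip(grid["cell_id"], counts_arr) if c}
    return grid, counts


class TestPoissonLLR:
    def test_null_identity(self):
        assert gscan.poisson_llr(10, 10.0, 100) == 0.0

    def test_spot_value(self):
        assert gscan.poisson_llr(20, 10.0, 100, "high") == pytest.approx(4.4403, abs=1e-3)

    def test_direction_condition(self):
        assert gscan.poisson_llr(20, 10.0, 100, "low") == 0.0
        assert gscan.poisson_llr(5, 10.0, 100, "low") > 0.0
        assert gscan.poisson_llr(5, 10.0, 100, "high") == 0.0

    def test_zero_and_total_conventions(self):
        assert gscan.poisson_llr(0, 10.0, 100, "low") > 0.0
        assert math.isfinite(gscan.poisson_llr(100, 10.0, 100, "high"))

    def test_degenerate_expectation_rejected(self):
        with pytest.raises(InvalidExpectationError):
            gscan.poisson_llr(10, 0.0, 100)
        with pytest.raises(InvalidExpectationError):
            gscan.poisson_llr(10, 100.0, 100)

    def test_monotone_in_c_above_E(self):
        vals = [gscan.poisson_llr(c, 10.0, 100, "high") for c in range(11, 40)]
        assert all(b > a for a, b in zip(vals, vals[1:]))


class TestRelativeRisk:
    def test_null(self):
        assert gscan.relative_risk(10, 10.0, 100) == pytest.approx(1.0)

    def test_exact_rational(self):
        assert gscan.relative_risk(20, 10.0, 100) == pytest.approx(2.25)

    def test_empty_cluster(self):
        assert gscan.relative_risk(0, 10.0, 100) == 0.0

    def test_all_cases_inside_is_infinite(self):
        assert gscan.relative_risk(100, 10.0, 100) == math.inf


class TestEnumerateWindows:
    def test_three_collinear_cells_pop_cap(self):
        grid = make_grid([500, 1500, 2500], [500, 500, 500], [100, 100, 100])
        cfg = gscan.ScanConfig(max_pop_fraction=0.34, n_replications=9)
        wins = gscan.enumerate_windows(grid, cfg)
        assert sorted(w.member_cells for w in wins) == [(0,), (1,), (2,)]

    def test_radius_cap_separates_distant_cells(self):
        grid = make_grid([0, 150_000], [0, 0], [10, 10])
        cfg = gscan.ScanConfig(max_radius_m=100_000, n_replications=9)
        wins = gscan.enumerate_windows(grid, cfg)
        for w in wins:
            assert len(w.member_cells) == 1

    def test_half_cap_two_equal_cells(self):
        grid = make_grid([500, 1500], [500, 500], [50, 50])
        cfg = gscan.ScanConfig(max_pop_fraction=0.5, n_replications=9)
        wins = gscan.enumerate_windows(grid, cfg)
        # {1,2} has population fraction 1.0 > 0.5 -> only the singletons
        assert sorted(w.member_cells for w in wins) == [(0,), (1,)]

    def test_deduplication(self):
        grid = make_grid([500, 1500], [500, 500], [50, 50])
        cfg = gscan.ScanConfig(max_pop_fraction=0.5, max_radius_m=5000, n_replications=9)
        wins = gscan.enumerate_windows(grid, cfg)
        assert len({frozenset(w.member_cells) for w in wins}) == len(wins)

    def test_empty_grid_is_error(self):
        with pytest.raises(NoCasesError):
            gscan.enumerate_windows(make_grid([], [], []), gscan.ScanConfig())


class TestScan:
    def test_config_validation(self):
        with pytest.raises(ConfigurationError):
            gscan.ScanConfig(max_pop_fraction=0.7)
        with pytest.raises(ConfigurationError):
            gscan.ScanConfig(n_replications=5)
        with pytest.raises(ConfigurationError):
            gscan.ScanConfig(direction="sideways")

    def test_no_cases_is_error(self):
        grid = make_grid([500, 1500], [500, 500], [50, 50])
        with pytest.raises(NoCasesError):
            gscan.scan(grid, {}, gscan.ScanConfig(n_replications=9))

    def test_unknown_cell_in_counts_is_error(self):
        grid = make_grid([500, 1500], [500, 500], [50, 50])
        with pytest.raises(DataIntegrityError):
            gscan.scan(grid, {77: 3}, gscan.ScanConfig(n_replications=9))

    def test_concentrated_cases_found_as_singleton(self):
        rng = np.random.default_rng(0)
        n = 25
        grid = make_grid(
            (np.arange(n) % 5 + 0.5) * 1000,
            (np.arange(n) // 5 + 0.5) * 1000,
            np.full(n, 100),
        )
        members, llr = gscan.most_likely_cluster(
            grid, {12: 50}, gscan.ScanConfig(n_replications=9)
        )
        assert members == (12,)
        assert llr > 0

    def test_p_value_floor_is_one_over_reps_plus_one(self):
        n = 16
        grid = make_grid(
            (np.arange(n) % 4 + 0.5) * 1000,
            (np.arange(n) // 4 + 0.5) * 1000,
            np.full(n, 100),
        )
        clusters = gscan.scan(
            grid, {5: 200}, gscan.ScanConfig(n_replications=999, seed=4)
        )
        assert clusters[0].p_value == pytest.approx(1 / 1000)

    def test_reported_clusters_do_not_overlap(self):
        rng = np.random.default_rng(3)
        n = 100
        grid = make_grid(
            (np.arange(n) % 10 + 0.5) * 1000,
            (np.arange(n) // 10 + 0.5) * 1000,
            np.full(n, 50),
        )
        counts = {0: 40, 99: 40}
        counts.update({int(c): 1 for c in rng.choice(np.arange(1, 99), 30, replace=False)})
        clusters = gscan.scan(grid, counts, gscan.ScanConfig(n_replications=99, seed=1))
        seen = set()
        for cl in clusters:
            assert not seen.intersection(cl.member_cells)
            seen.update(cl.member_cells)
        assert [cl.rank for cl in clusters] == list(range(1, len(clusters) + 1))

    def test_population_scaling_leaves_llr_invariant(self):
        rng = np.random.default_rng(8)
        grid, counts = random_small_grid(rng)
        cfg = gscan.ScanConfig(n_replications=9)
        _, llr1 = gscan.most_likely_cluster(grid, counts, cfg)
        scaled = grid.assign(population=grid["population"] * 17)
        _, llr2 = gscan.most_likely_cluster(scaled, counts, cfg)
        assert llr2 == pytest.approx(llr1, rel=1e-12)

    def test_seed_determinism(self):
        rng = np.random.default_rng(5)
        grid, counts = random_small_grid(rng)
        cfg = gscan.ScanConfig(n_replications=99, seed=42)
        a = gscan.scan(grid, counts, cfg)
        b = gscan.scan(grid, counts, cfg)
        assert [(c.member_cells, c.llr, c.p_value) for c in a] == [
            (c.member_cells, c.llr, c.p_value) for c in b
        ]

    @pytest.mark.parametrize("direction", ["high", "low"])
    @pytest.mark.parametrize("seed", range(8))
    def test_oracle_equivalence_small_grids(self, seed, direction):
        rng = np.random.default_rng(1000 + seed)
        grid, counts = random_small_grid(rng)
        cfg = gscan.ScanConfig(
            max_pop_fraction=float(rng.uniform(0.1, 0.5)),
            max_radius_m=float(rng.uniform(1500, 6000)),
            n_replications=9,
            direction=direction,
        )
        members, llr = gscan.most_likely_cluster(grid, counts, cfg)
        oracle_members, oracle_llr = brute_force_best(grid, counts, cfg)
        assert llr == pytest.approx(oracle_llr, abs=1e-9)
        if oracle_llr > 0:
            assert frozenset(members) == oracle_members


class TestRunAllWindows:
    def test_eight_result_sets(self, small_cases, small_grid):
        from gridepi import windows as win

        assignments = win.assign_all(small_cases)
        cfg = gscan.ScanConfig(n_replications=19, seed=2)
        results = gscan.run_all_windows(assignments, small_grid, cfg)
        assert len(results) == 8
        assert set(results) == {
            (w, d) for w in win.WINDOWS for d in ("high", "low")
        }
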