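"""Agent movement rules: Lévy sampling, heading choice, cone, walks, runs."""

import numpy as np
import pytest
from scipy import stats

from paleowalk.cost_surface import CostSurface
from paleowalk.raster_core import CellCoord
from paleowalk.synthetic_landscape import SynthConfig, make_corridor_world, make_landscape, make_uniform_plain
from paleowalk.walker_engine import (
    BEARING_OFFSETS,
    BEARINGS,
    AgentState,
    LevyParams,
    LevySampler,
    ScenarioConfig,
    choose_heading_360,
    cone_neighbors,
    do_levy_walk,
    draw_levy_length,
    is_new_territory,
    run_scenario,
)


def _surface(cost: np.ndarray, barrier=None) -> CostSurface:
    return CostSurface.from_arrays(np.asarray(cost, dtype=float), barrier)


class TestLevySampler:
    def test_u_zero_gives_minimum(self):
        p = LevyParams(mu=2.0, l_min=3, l_max=50)
        assert draw_levy_length(0.0, p) == 3

    def test_degenerate_support(self):
        p = LevyParams(mu=2.0, l_min=3, l_max=3)
        assert all(draw_levy_length(u, p) == 3 for u in (0.0, 0.4, 0.999))

    def test_monotone_in_u(self):
        sampler = LevySampler(LevyParams(mu=1.5, l_min=1, l_max=40))
        draws = [sampler.draw(u) for u in np.linspace(0, 0.999, 200)]
        assert draws == sorted(draws)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            draw_levy_length(1.0, LevyParams())

    def test_chi_square_against_mass_function(self):
        """10^6 seeded draws match the normalised l^-2 mass function."""
        p = LevyParams(mu=2.0, l_min=1, l_max=100)
        sampler = LevySampler(p)
        rng = np.random.default_rng(123)
        draws = sampler.draw_many(rng.random(1_000_000))
        observed = np.bincount(draws, minlength=101)[1:101]
        expected = sampler.pmf * len(draws)
        # pool any sparse tail so every expected count is >= 5
        keep = expected >= 5
        obs, exp = observed[keep], expected[keep]
        if not keep.all():
            obs = np.append(obs, observed[~keep].sum())
            exp = np.append(exp, expected[~keep].sum())
        chi2 = stats.chisquare(obs, exp * obs.sum() / exp.sum())
        assert chi2.pvalue > 0.01


class TestHeadingChoice:
    def test_single_open_neighbor(self):
        barrier = np.ones((3, 3), dtype=bool)
        barrier[1, 1] = False
        barrier[0, 1] = False  # only north open
        s = AgentState(position=CellCoord(1, 1))
        cs = _surface(np.ones((3, 3)), barrier)
        rng = np.random.default_rng(0)
        assert choose_heading_360(s, cs, LevyParams(), rng) == 0

    def test_trapped_agent_returns_none(self):
        barrier = np.ones((3, 3), dtype=bool)
        barrier[1, 1] = False
        s = AgentState(position=CellCoord(1, 1))
        cs = _surface(np.ones((3, 3)), barrier)
        assert choose_heading_360(s, cs, LevyParams(), np.random.default_rng(0)) is None

    def test_uniform_tie_break_frequencies(self):
        """All-equal costs: each of the 8 bearings drawn ~1/8 of the time."""
        cs = _surface(np.ones((3, 3)))
        rng = np.random.default_rng(99)
        p = LevyParams()
        counts = {b: 0 for b in BEARINGS}
        n = 100_000
        for _ in range(n):
            s = AgentState(position=CellCoord(1, 1))
            counts[choose_heading_360(s, cs, p, rng)] += 1
        freqs = np.array([counts[b] / n for b in BEARINGS])
        assert np.all(np.abs(freqs - 0.125) <= 0.01)

    def test_memory_fallback_picks_global_minimum(self):
        cost = np.arange(9, dtype=float).reshape(3, 3) + 1.0
        cs = _surface(cost)
        s = AgentState(position=CellCoord(1, 1))
        for b in BEARINGS:  # every neighbour freshly visited
            dr, dc = BEARING_OFFSETS[b]
            s.last_visit[(1 + dr, 1 + dc)] = 0
        s.global_step = 1
        heading = choose_heading_360(s, cs, LevyParams(), np.random.default_rng(0))
        assert heading == 315  # cell (0,0) holds the cheapest cost


class TestCone:
    @pytest.mark.parametrize(
        "heading,expected",
        [
            (0, {(-1, -1), (-1, 0), (-1, 1)}),  # N -> NW, N, NE offsets
            (90, {(-1, 1), (0, 1), (1, 1)}),
            (225, {(1, 0), (1, -1), (0, -1)}),
        ],
    )
    def test_three_forward_cells(self, heading, expected):
        s = AgentState(position=CellCoord(5, 5), heading_deg=heading)
        got = {(c.row - 5, c.col - 5) for c in cone_neighbors(s)}
        assert got == expected

    @pytest.mark.parametrize("heading", BEARINGS)
    def test_cell_behind_never_in_cone(self, heading):
        s = AgentState(position=CellCoord(5, 5), heading_deg=heading)
        behind = BEARING_OFFSETS[(heading + 180) % 360]
        assert (5 + behind[0], 5 + behind[1]) not in {
            (c.row, c.col) for c in cone_neighbors(s)
        }


class TestNewTerritory:
    def test_fresh_agent_sees_new_territory(self):
        s = AgentState(position=CellCoord(5, 5))
        assert is_new_territory(s, LevyParams())

    def test_fully_visited_neighborhood_is_old(self):
        s = AgentState(position=CellCoord(5, 5))
        for b in BEARINGS:
            dr, dc = BEARING_OFFSETS[b]
            s.last_visit[(5 + dr, 5 + dc)] = 0
        s.global_step = 1
        assert not is_new_territory(s, LevyParams())

    def test_threshold_boundary_five_of_eight(self):
        p = LevyParams(new_territory_min_unvisited=5)
        for n_visited, expect in [(3, True), (4, False)]:
            s = AgentState(position=CellCoord(5, 5))
            for b in BEARINGS[:n_visited]:
                dr, dc = BEARING_OFFSETS[b]
                s.last_visit[(5 + dr, 5 + dc)] = 0
            s.global_step = 1
            assert is_new_territory(s, p) is expect


class TestLevyWalk:
    def test_open_plain_walk_structure(self):
        cs = _surface(np.ones((50, 50)))
        p = LevyParams(mu=2.0, l_min=5, l_max=5, doubling_factor=1)
        s = AgentState(position=CellCoord(25, 25))
        s.visit(s.position)
        path, trapped = do_levy_walk(s, cs, p, np.random.default_rng(4))
        assert not trapped and len(path) == 5
        prev = CellCoord(25, 25)
        for cell in path:
            assert prev.is_adjacent8(cell)
            prev = cell

    def test_corridor_confines_steps(self):
        """A zero-extra-cost corridor flanked by dearer cells holds the walk."""
        cost = np.full((3, 30), 5.0)
        cost[1, :] = 1.0
        cs = _surface(cost)
        p = LevyParams(mu=2.0, l_min=20, l_max=20, doubling_factor=1)
        s = AgentState(position=CellCoord(1, 0), heading_deg=90)
        s.visit(s.position)
        path, trapped = do_levy_walk(s, cs, p, np.random.default_rng(0))
        assert not trapped
        assert all(c.row == 1 for c in path)

    def test_boxed_in_agent_is_trapped(self):
        barrier = np.ones((3, 3), dtype=bool)
        barrier[1, 1] = False
        cs = _surface(np.ones((3, 3)), barrier)
        s = AgentState(position=CellCoord(1, 1))
        path, trapped = do_levy_walk(s, cs, LevyParams(), np.random.default_rng(0))
        assert trapped and path == []


class TestRunScenario:
    def test_zero_walks_records_only_start(self, uniform_plain):
        t = run_scenario(ScenarioConfig(cost_surface=uniform_plain, n_walks=0, seed=5))
        assert len(t) == 1 and t.n_steps == 0

    def test_fixed_seed_bit_identical(self, uniform_plain):
        cfg = ScenarioConfig(cost_surface=uniform_plain, n_walks=300, seed=17)
        a, b = run_scenario(cfg), run_scenario(cfg)
        assert np.array_equal(a.rows, b.rows)
        assert np.array_equal(a.cols, b.cols)
        assert np.array_equal(a.walk_index, b.walk_index)

    def test_no_valid_start_raises(self):
        barrier = np.ones((4, 4), dtype=bool)
        barrier[0, 0] = False
        cs = _surface(np.ones((4, 4)), barrier)
        from shapely.geometry import box

        region = box(2.0, 0.0, 4.0, 2.0)  # passable cell (0,0) lies outside
        with pytest.raises(ValueError, match="start region"):
            run_scenario(ScenarioConfig(cost_surface=cs, start_region=region, n_walks=1, seed=0))

    def test_trajectory_invariants_on_fuzzed_landscapes(self):
        """Adjacency and barrier avoidance on random synthetic worlds."""
        from paleowalk.cost_surface import build_cost_surface

        for seed in range(5):
            stack = make_landscape(SynthConfig(n_rows=40, n_cols=40, seed=seed))
            cs = build_cost_surface(
                stack["dem"], stack["precip"], stack["glacier_mask"],
                stack["water_mask"], stack["rivers"],
            )
            t = run_scenario(ScenarioConfig(cost_surface=cs, n_walks=400, seed=seed))
            barrier = cs.barrier_mask
            assert not barrier[t.rows, t.cols].any()
            dr = np.abs(np.diff(t.rows))
            dc = np.abs(np.diff(t.cols))
            assert np.all(np.maximum(dr, dc) == 1)

    def test_per_step_choice_matches_argmin_oracle(self, uniform_plain):
        """Replay a recorded run and re-derive each within-walk step's
        candidate pool; the step taken must be a minimum-cost member."""
        stack = make_landscape(SynthConfig(n_rows=40, n_cols=40, seed=2))
        from paleowalk.cost_surface import build_cost_surface

        cs = build_cost_surface(
            stack["dem"], stack["precip"], stack["glacier_mask"],
            stack["water_mask"], stack["rivers"],
        )
        p = LevyParams()
        t = run_scenario(ScenarioConfig(cost_surface=cs, n_walks=300, seed=8, levy=p))
        barrier = cs.barrier_mask
        cost = cs.cost.values
        last_visit: dict = {(int(t.rows[0]), int(t.cols[0])): 0}
        checked = 0
        for k in range(1, len(t)):
            r0, c0 = int(t.rows[k - 1]), int(t.cols[k - 1])
            r1, c1 = int(t.rows[k]), int(t.cols[k])
            same_walk = k >= 2 and t.walk_index[k] == t.walk_index[k - 1]
            if same_walk:
                heading = {(-1, 0): 0, (-1, 1): 45, (0, 1): 90, (1, 1): 135,
                           (1, 0): 180, (1, -1): 225, (0, -1): 270, (-1, -1): 315}[
                    (r0 - int(t.rows[k - 2]), c0 - int(t.cols[k - 2]))
                ]
                cands = []
                for rel in (-45, 0, 45):
                    dr, dc = BEARING_OFFSETS[(heading + rel) % 360]
                    rr, cc = r0 + dr, c0 + dc
                    if 0 <= rr < 40 and 0 <= cc < 40 and not barrier[rr, cc]:
                        cands.append((rr, cc))
                fresh = [
                    (rr, cc) for rr, cc in cands
                    if (rr, cc) not in last_visit or k - last_visit[(rr, cc)] >= p.memory_horizon
                ]
                pool = fresh if fresh else cands
                best = min(cost[rr, cc] for rr, cc in pool)
                assert cost[r1, c1] == best and (r1, c1) in pool
                checked += 1
            last_visit[(r1, c1)] = k
        assert checked >= 100  # the oracle exercised a real sample of steps

    def test_corridor_emergence(self):
        """Steps concentrate on a cheap corridor far beyond its area share."""
        cs = make_corridor_world(61, 1.0, 1.74)
        corridor_row = 61 // 2
        in_corridor = total = 0
        for seed in range(10):
            t = run_scenario(ScenarioConfig(cost_surface=cs, n_walks=1500, seed=seed))
            in_corridor += int((t.rows == corridor_row).sum())
            total += len(t)
        area_fraction = 1.0 / 61
        test = stats.binomtest(in_corridor, total, area_fraction, alternative="greater")
        assert test.pvalue < 0.001
        assert in_corridor / total > area_fraction
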