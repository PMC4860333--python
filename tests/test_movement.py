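import math

import numpy as np
import pytest

import hornwalk as hw
from hornwalk.movement import MOORE_OFFSETS


def _adjacent(a, b):
    return max(abs(a.row - b.row), abs(a.col - b.col)) == 1


# --------------------------------------------------------------- candidates

def test_interior_agent_gets_all_eight_neighbors(open_landscape):
    agent = hw.Agent(current=hw.Cell(4, 4))
    cands = hw.neighbor_candidates(open_landscape, agent, np.random.default_rng(0))
    assert len(cands) == 8
    assert set(cands) == {hw.Cell(4 + dr, 4 + dc) for dr, dc in MOORE_OFFSETS}


def test_previous_cell_is_excluded(open_landscape):
    agent = hw.Agent(current=hw.Cell(4, 4), previous=hw.Cell(4, 3))
    cands = hw.neighbor_candidates(open_landscape, agent, np.random.default_rng(0))
    assert len(cands) == 7
    assert hw.Cell(4, 3) not in cands


def test_corner_agent_sees_exit_markers(open_landscape):
    agent = hw.Agent(current=hw.Cell(0, 0))
    cands = hw.neighbor_candidates(open_landscape, agent, np.random.default_rng(0))
    assert len(cands) == 8
    in_extent = [c for c in cands if open_landscape.in_extent(c)]
    assert len(in_extent) == 3
    assert sum(1 for c in cands if not open_landscape.in_extent(c)) == 5


def test_candidate_order_is_a_seeded_permutation(open_landscape):
    agent = hw.Agent(current=hw.Cell(4, 4))
    a = hw.neighbor_candidates(open_landscape, agent, np.random.default_rng(42))
    b = hw.neighbor_candidates(open_landscape, agent, np.random.default_rng(42))
    assert a == b
    orders = {tuple(hw.neighbor_candidates(open_landscape, agent,
                                           np.random.default_rng(s)))
              for s in range(30)}
    assert len(orders) > 1  # actually shuffled


# --------------------------------------------------------------- evaluation

class _RiggedRng:
    """Stands in for a Generator, returning scripted uniform draws."""

    def __init__(self, draws):
        self.draws = list(draws)
        self.consumed = 0

    def uniform(self, lo, hi):
        self.consumed += 1
        return self.draws.pop(0)


def _distance_strip(n_cols=9):
    """1 x n strip with escape terrain at col 0; col c is 75c metres away."""
    slope = np.zeros((1, n_cols))
    slope[0, 0] = 45.0
    zeros = np.zeros((1, n_cols), dtype=np.int64)
    return hw.make_toy_landscape(slope, np.zeros((1, n_cols)), zeros, zeros)


def test_within_400m_accepted_without_a_draw(rules):
    land = _distance_strip()
    rng = _RiggedRng([0.0])
    assert hw.evaluate_candidate(land, hw.Cell(0, 5), rules, rng)  # 375 m
    assert rng.consumed == 0


def test_impassable_rejected_without_a_draw(rules):
    land = hw.make_toy_landscape([[45.0, 0.0]], [[0.0, 0.0]], [[0, 0]], [[0, 1]])
    rng = _RiggedRng([0.0])
    assert not hw.evaluate_candidate(land, hw.Cell(0, 1), rules, rng)
    assert rng.consumed == 0


def test_beyond_400m_draw_compared_strictly_to_probability(rules):
    land = _distance_strip()  # col 6 -> 450 m, p = 91.611...
    p450 = 188.21 * math.exp(-0.0016 * 450)
    assert hw.evaluate_candidate(land, hw.Cell(0, 6), rules, _RiggedRng([50.0]))
    assert not hw.evaluate_candidate(land, hw.Cell(0, 6), rules, _RiggedRng([95.0]))
    assert not hw.evaluate_candidate(land, hw.Cell(0, 6), rules, _RiggedRng([p450]))


def test_acceptance_rate_matches_probability_curve(rules):
    """Empirical acceptance over 1e5 draws tracks min(1, p(d)/100) at 600 m."""
    land = _distance_strip()
    cell = hw.Cell(0, 8)  # 600 m
    p = hw.movement_probability(600.0, rules) / 100.0
    assert p < 1
    n = 100_000
    rng = np.random.default_rng(2024)
    hits = sum(hw.evaluate_candidate(land, cell, rules, rng) for _ in range(n))
    se = math.sqrt(p * (1 - p) / n)
    assert abs(hits / n - p) < 3 * se


# ------------------------------------------------------------------ stepping

def _sealed_cell_landscape():
    """Single passable escape cell surrounded by water."""
    slope = np.zeros((3, 3))
    slope[1, 1] = 45.0
    water = np.ones((3, 3), dtype=np.int64)
    water[1, 1] = 0
    zeros = np.zeros((3, 3), dtype=np.int64)
    return hw.make_toy_landscape(slope, np.zeros((3, 3)), water, zeros)


def test_agent_surrounded_by_water_is_stuck(rules):
    land = _sealed_cell_landscape()
    agent = hw.Agent(current=hw.Cell(1, 1))
    out = hw.step_agent(land, agent, rules, np.random.default_rng(0))
    assert out.kind == "removed" and out.reason == "stuck"
    traj = hw.run_agent(land, hw.Cell(1, 1), rules, np.random.default_rng(0))
    assert len(traj) == 1 and traj.removal_reason == "stuck"


def test_step_cap_removes_before_any_move(open_landscape, rules):
    agent = hw.Agent(current=hw.Cell(4, 4), steps_taken=rules.max_steps)
    out = hw.step_agent(open_landscape, agent, rules, np.random.default_rng(0))
    assert out.kind == "removed" and out.reason == "max_steps"
    assert agent.current == hw.Cell(4, 4)


def test_normal_move_is_adjacent_and_not_backwards(open_landscape, rules):
    agent = hw.Agent(current=hw.Cell(4, 4), previous=hw.Cell(4, 3))
    out = hw.step_agent(open_landscape, agent, rules, np.random.default_rng(7))
    assert out.kind == "moved"
    assert _adjacent(out.destination, hw.Cell(4, 4))
    assert out.destination != hw.Cell(4, 3)


def test_corridor_walk_equals_unique_path_oracle(corridor_landscape, rules):
    for seed in range(20):
        traj = hw.run_agent(corridor_landscape, hw.Cell(1, 1), rules,
                            np.random.default_rng(seed))
        assert [c for c in traj.cells] == [hw.Cell(1, c) for c in range(1, 6)]
        assert traj.removal_reason == "stuck"


def test_impassable_seed_rejected(rules):
    land = hw.make_toy_landscape([[45.0, 0.0]], [[0.0, 0.0]], [[0, 1]], [[0, 0]])
    with pytest.raises(ValueError, match="passable"):
        hw.run_agent(land, hw.Cell(0, 1), rules, np.random.default_rng(0))


def test_run_agent_matches_step_agent_stream(open_landscape, rules):
    """The fast inlined walk consumes the RNG exactly like step_agent."""
    short = rules.with_overrides(max_steps=50)
    traj = hw.run_agent(open_landscape, hw.Cell(4, 4), short,
                        np.random.default_rng(11))
    agent = hw.Agent(current=hw.Cell(4, 4))
    rng = np.random.default_rng(11)
    cells = [agent.current]
    compiled = hw.compile_rules(open_landscape, short)
    while True:
        out = hw.step_agent(open_landscape, agent, short, rng, compiled=compiled)
        if out.kind == "removed":
            reason = out.reason
            break
        cells.append(out.destination)
    assert cells == traj.cells and reason == traj.removal_reason


def test_trajectory_invariants_over_many_random_walks(synthetic_landscape, rules):
    """Adjacency, no-backtrack and barrier avoidance on ~1e4 trajectories."""
    land = synthetic_landscape
    short = rules.with_overrides(max_steps=30)
    compiled = hw.compile_rules(land, short)
    suitable = hw.suitable_cells(land, short)
    passable = compiled.passable
    n_checked = 0
    for k in range(10_000):
        rng = np.random.default_rng(
            np.random.SeedSequence(99, spawn_key=(k,)))
        r, c = suitable[rng.integers(len(suitable))]
        traj = hw.run_agent(land, hw.Cell(int(r), int(c)), short, rng,
                            compiled=compiled)
        cells = traj.cells
        for a, b in zip(cells, cells[1:]):
            assert _adjacent(a, b)
        for t in range(1, len(cells) - 1):
            assert cells[t + 1] != cells[t - 1]
        for cell in cells:
            assert passable[cell.row, cell.col]
        n_checked += len(cells)
    assert n_checked > 10_000


def test_identical_seed_gives_bit_identical_trajectory(synthetic_landscape, rules):
    a = hw.run_agent(synthetic_landscape, hw.Cell(30, 30),
                     rules, np.random.default_rng(5))
    b = hw.run_agent(synthetic_landscape, hw.Cell(30, 30),
                     rules, np.random.default_rng(5))
    assert a.cells == b.cells and a.removal_reason == b.removal_reason


# ------------------------------------------------- independent 5x5 oracle

def _reference_walk(land, rules, seed_cell, rng, max_steps):
    """Straight-line re-implementation of the decision heuristic.

    Works directly off the raw layer arrays with its own brute-force
    escape distance; shares only the RNG stream convention (shuffle,
    then one draw per beyond-threshold candidate in list order).
    """
    slope = np.asarray(land.slope.values, dtype=float)
    cover = np.asarray(land.cover.values, dtype=float)
    water = np.asarray(land.water.values) != 0
    roads = np.asarray(land.roads.values) != 0
    n_rows, n_cols = slope.shape
    cs = land.cell_size
    esc = [(r, c) for r in range(n_rows) for c in range(n_cols)
           if slope[r, c] > rules.slope_threshold_deg]

    def dist(r, c):
        return min(math.hypot(r - er, c - ec) * cs for er, ec in esc)

    cells = [seed_cell]
    cur, prev = tuple(seed_cell), None
    steps = 0
    while True:
        if steps >= max_steps:
            return cells, "max_steps"
        neigh = [(cur[0] + dr, cur[1] + dc) for dr, dc in MOORE_OFFSETS]
        if prev is not None:
            neigh = [n for n in neigh if n != prev]
        neigh = [neigh[i] for i in rng.permutation(len(neigh))]
        moved = False
        for r, c in neigh:
            if not (0 <= r < n_rows and 0 <= c < n_cols):
                return cells, "left_extent"
            if water[r, c] or roads[r, c] or cover[r, c] > rules.cover_threshold_pct:
                continue
            d = dist(r, c)
            if d > rules.escape_accept_dist_m:
                p = rules.prob_coef_a * math.exp(-rules.prob_rate_b * d)
                if not rng.uniform(0.0, 100.0) < p:
                    continue
            prev, cur = cur, (r, c)
            cells.append(hw.Cell(r, c))
            steps += 1
            moved = True
            break
        if not moved:
            return cells, "stuck"


def test_walk_matches_independent_reference_on_5x5(rules):
    slope = [[0, 0, 0, 0, 0],
             [0, 45, 0, 0, 0],
             [0, 0, 0, 0, 0],
             [0, 0, 0, 50, 0],
             [0, 0, 0, 0, 0]]
    cover = [[0, 60, 0, 0, 0],
             [0, 0, 0, 45, 0],
             [0, 0, 0, 0, 0],
             [0, 0, 80, 0, 0],
             [0, 0, 0, 0, 0]]
    water = [[0, 0, 1, 0, 0],
             [0, 0, 0, 0, 0],
             [0, 1, 0, 0, 0],
             [0, 0, 0, 0, 0],
             [0, 0, 0, 0, 1]]
    roads = [[0, 0, 0, 0, 0],
             [0, 0, 0, 0, 0],
             [0, 0, 0, 1, 0],
             [0, 0, 0, 0, 0],
             [0, 1, 0, 0, 0]]
    # 150 m cells so the far corner sits beyond 400 m and draws are exercised
    land = hw.make_toy_landscape(slope, cover, water, roads, cell_size=150.0)
    short = hw.DEFAULT_RULES.with_overrides(max_steps=40)
    for seed in range(25):
        got = hw.run_agent(land, hw.Cell(2, 2), short, np.random.default_rng(seed))
        want_cells, want_reason = _reference_walk(
            land, short, hw.Cell(2, 2), np.random.default_rng(seed), 40)
        assert got.cells == want_cells
        assert got.removal_reason == want_reason
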