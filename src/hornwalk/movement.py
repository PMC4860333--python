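"""Per-step decision heuristic and single-agent walks.

An agent is a pseudo-biased random walk on the raster: each time step it
shuffles its eight Moore neighbours (minus the cell it came from — no
backtracking), then evaluates them in shuffled order.  A candidate is
rejected outright if impassable (road, water, dense crown cover,
nodata); accepted outright if within the deterministic-acceptance
distance of escape terrain (400 m by default); otherwise accepted with
probability ``min(1, p(d)/100)`` where ``p(d) = 188.21 e^{-0.0016 d}``
percent, decided by a single uniform draw on (0, 100) compared strictly
against ``p(d)``.  The first accepted candidate becomes the move; a
shuffled-in out-of-extent neighbour, if reached, removes the agent
(``left_extent``); exhausting the list removes it (``stuck``); agents
are also removed after 2,000 moves (``max_steps``).

RNG stream order per step: one shuffle of the candidate list, then one
draw per beyond-threshold candidate in list order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .landscape import Cell, MovementRules, RasterLandscape, movement_probability

__all__ = [
    "Agent",
    "Trajectory",
    "StepOutcome",
    "RemovalReason",
    "MOORE_OFFSETS",
    "neighbor_candidates",
    "evaluate_candidate",
    "step_agent",
    "run_agent",
    "CompiledRules",
    "compile_rules",
]

#: The 8 Moore-neighbourhood offsets, row-major scan order (before shuffling).
MOORE_OFFSETS: tuple[tuple[int, int], ...] = (
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
)

STUCK = "stuck"
LEFT_EXTENT = "left_extent"
MAX_STEPS = "max_steps"
RemovalReason = str


@dataclass
class Agent:
    """Walker state: current cell, the previous cell (if any), moves made."""

    current: Cell
    previous: Cell | None = None
    steps_taken: int = 0


@dataclass
class StepOutcome:
    kind: str  # "moved" | "removed"
    destination: Cell | None = None
    reason: RemovalReason | None = None


@dataclass
class Trajectory:
    """Ordered cells visited by one agent, seed first, plus why it stopped."""

    cells: list[Cell]
    removal_reason: RemovalReason
    rng_seed_record: int | None = None

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def n_moves(self) -> int:
        return len(self.cells) - 1


@dataclass
class CompiledRules:
    """Per-cell lookups precomputed for fast stepping.

    ``accept`` marks cells taken without a draw (passable and within the
    deterministic-acceptance distance); ``prob`` holds the percent
    acceptance probability used beyond it.
    """

    passable: np.ndarray
    accept: np.ndarray
    prob: np.ndarray
    rules: MovementRules
    n_rows: int
    n_cols: int


def compile_rules(landscape: RasterLandscape, rules: MovementRules) -> CompiledRules:
    passable = landscape.passable_grid(rules)
    dist = landscape.escape_distance
    accept = passable & (dist <= rules.escape_accept_dist_m)
    with np.errstate(over="ignore"):
        prob = rules.prob_coef_a * np.exp(-rules.prob_rate_b * dist)
    return CompiledRules(
        passable=passable,
        accept=accept,
        prob=prob,
        rules=rules,
        n_rows=landscape.n_rows,
        n_cols=landscape.n_cols,
    )


def neighbor_candidates(
    landscape: RasterLandscape, agent: Agent, rng: np.random.Generator
) -> list[Cell]:
    """Shuffled Moore neighbours of the agent, excluding its previous cell.

    Out-of-extent neighbours stay in the list as exit markers (cells with
    indices outside the raster); selecting one removes the agent.
    """
    r, c = agent.current
    cells = [Cell(r + dr, c + dc) for dr, dc in MOORE_OFFSETS]
    if agent.previous is not None:
        cells = [cell for cell in cells if cell != agent.previous]
    order = rng.permutation(len(cells))
    return [cells[i] for i in order]


def evaluate_candidate(
    landscape: RasterLandscape,
    cell: Cell,
    rules: MovementRules | None = None,
    rng: np.random.Generator | None = None,
) -> bool:
    """Accept or reject one in-extent candidate cell.

    Impassable cells are rejected without a draw; cells within the
    deterministic-acceptance distance of escape terrain are accepted
    without a draw; otherwise a uniform draw on (0, 100) must fall
    strictly below the movement probability (so probabilities >= 100
    always accept).
    """
    from .landscape import is_passable

    rules = rules or landscape.rules
    if not is_passable(landscape, cell, rules):
        return False
    dist = float(landscape.escape_distance[cell.row, cell.col])
    if dist <= rules.escape_accept_dist_m:
        return True
    if rng is None:
        raise ValueError("rng required for probabilistic acceptance")
    draw = rng.uniform(0.0, 100.0)
    return draw < movement_probability(dist, rules)


def _evaluate_compiled(
    compiled: CompiledRules, row: int, col: int, rng: np.random.Generator
) -> bool:
    if not compiled.passable[row, col]:
        return False
    if compiled.accept[row, col]:
        return True
    return rng.uniform(0.0, 100.0) < compiled.prob[row, col]


def step_agent(
    landscape: RasterLandscape,
    agent: Agent,
    rules: MovementRules | None = None,
    rng: np.random.Generator | None = None,
    compiled: CompiledRules | None = None,
) -> StepOutcome:
    """Advance the agent one time step, or remove it.

    Mutates ``agent`` in place on a move.  The step-cap check precedes
    any candidate evaluation, so an agent at the cap makes no further
    move.
    """
    if compiled is None:
        compiled = compile_rules(landscape, rules or landscape.rules)
    if agent.steps_taken >= compiled.rules.max_steps:
        return StepOutcome(kind="removed", reason=MAX_STEPS)
    if rng is None:
        raise ValueError("rng is required")
    n_rows, n_cols = compiled.n_rows, compiled.n_cols
    for cell in neighbor_candidates(landscape, agent, rng):
        r, c = cell
        if not (0 <= r < n_rows and 0 <= c < n_cols):
            return StepOutcome(kind="removed", reason=LEFT_EXTENT)
        if _evaluate_compiled(compiled, r, c, rng):
            agent.previous = agent.current
            agent.current = cell
            agent.steps_taken += 1
            return StepOutcome(kind="moved", destination=cell)
    return StepOutcome(kind="removed", reason=STUCK)


def run_agent(
    landscape: RasterLandscape,
    seed_cell: Cell,
    rules: MovementRules | None = None,
    rng: np.random.Generator | None = None,
    compiled: CompiledRules | None = None,
    seed_record: int | None = None,
) -> Trajectory:
    """Walk one agent from ``seed_cell`` until removal.

    The returned trajectory records every occupied cell in order,
    starting with the seed, and the removal reason.
    """
    if compiled is None:
        compiled = compile_rules(landscape, rules or landscape.rules)
    if rng is None:
        raise ValueError("rng is required")
    if not landscape.in_extent(seed_cell):
        raise ValueError(f"seed cell {seed_cell} is outside the raster extent")
    if not compiled.passable[seed_cell.row, seed_cell.col]:
        raise ValueError(f"seed cell {seed_cell} is not passable")

    # Inlined stepping loop (same semantics as step_agent) — this is the
    # hot path for the 20,000-iteration scenario runs.
    max_steps = compiled.rules.max_steps
    passable = compiled.passable
    accept = compiled.accept
    prob = compiled.prob
    n_rows, n_cols = compiled.n_rows, compiled.n_cols
    uniform = rng.uniform
    permutation = rng.permutation

    cells = [seed_cell]
    cur_r, cur_c = seed_cell
    prev: tuple[int, int] | None = None
    steps = 0
    reason: RemovalReason
    while True:
        if steps >= max_steps:
            reason = MAX_STEPS
            break
        cand = [(cur_r + dr, cur_c + dc) for dr, dc in MOORE_OFFSETS]
        if prev is not None:
            cand.remove(prev)
        order = permutation(len(cand))
        moved = False
        removed = False
        for i in order:
            r, c = cand[i]
            if not (0 <= r < n_rows and 0 <= c < n_cols):
                reason = LEFT_EXTENT
                removed = True
                break
            if not passable[r, c]:
                continue
            if not accept[r, c] and not uniform(0.0, 100.0) < prob[r, c]:
                continue
            prev = (cur_r, cur_c)
            cur_r, cur_c = r, c
            steps += 1
            cells.append(Cell(r, c))
            moved = True
            break
        if removed:
            break
        if not moved:
            reason = STUCK
            break
    return Trajectory(cells=cells, removal_reason=reason, rng_seed_record=seed_record)
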