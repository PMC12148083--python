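"""Agent-based least-cost-path Lévy walker.

One agent moves over a static cost raster.  Each walk begins with a
360-degree look: the agent faces the cheapest of its eight neighbours that
it has not recently occupied.  It then takes a number of steps drawn from
a truncated power law P(l) ∝ l^(-mu); while walking it only considers the
three cells inside a 100-degree forward cone (relative bearings -45, 0,
+45 — never the cells behind itself), again moving to the cheapest
non-recent one and updating its heading to the direction moved.  An agent
standing in "new territory" — most of its neighbourhood not recently
occupied — doubles the drawn walk length, the colonisation rule that
produces rare long-distance moves.

Route choice therefore emerges from local cost minimisation only: the
agent has no destination and no global knowledge.  All randomness (start
cell, Lévy draws, cost tie-breaks) comes from a single seeded generator in
a fixed consumption order, so a run is bit-reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry.base import BaseGeometry

from . import raster_core
from .cost_surface import CostSurface
from .raster_core import CellCoord, GridRaster

__all__ = [
    "LevyParams",
    "AgentState",
    "ScenarioConfig",
    "Trajectory",
    "LevySampler",
    "draw_levy_length",
    "choose_heading_360",
    "cone_neighbors",
    "is_new_territory",
    "do_levy_walk",
    "run_scenario",
    "BEARINGS",
    "BEARING_OFFSETS",
]

#: The eight compass bearings (deg clockwise from north) and their grid
#: offsets under the row-0-north convention.
BEARINGS: tuple[int, ...] = (0, 45, 90, 135, 180, 225, 270, 315)
BEARING_OFFSETS: dict[int, tuple[int, int]] = {
    0: (-1, 0), 45: (-1, 1), 90: (0, 1), 135: (1, 1),
    180: (1, 0), 225: (1, -1), 270: (0, -1), 315: (-1, -1),
}
_OFFSET_BEARING = {v: k for k, v in BEARING_OFFSETS.items()}


def step_bearing(dr: int, dc: int) -> int:
    """Bearing (deg) of a single king-move step."""
    return _OFFSET_BEARING[(dr, dc)]


@dataclass
class LevyParams:
    """Movement-rule parameters.

    mu : power-law exponent of the walk-length distribution (> 1).  The
        shipped default (2.93) is calibrated so that, with the other
        defaults, an agent on an open uniform 300x300 plain averages about
        2.075 steps per walk — the published behaviour of roughly 830,000
        steps per 400,000 walks (scripts/calibrate_levy.py regenerates it).
    l_min, l_max : inclusive truncation bounds of the walk length (steps).
    memory_horizon : a cell counts as "recently occupied" if it was visited
        within this many global steps.
    new_territory_min_unvisited : number of the 8 neighbours that must be
        non-recent for the neighbourhood to count as new territory
        (default 5, i.e. most of them).
    doubling_factor : walk-length multiplier applied in new territory; the
        doubled length is capped at l_max * doubling_factor.
    """

    mu: float = 2.93
    l_min: int = 1
    l_max: int = 100
    memory_horizon: int = 10_000
    new_territory_min_unvisited: int = 5
    doubling_factor: int = 2

    def __post_init__(self) -> None:
        if self.mu <= 1:
            raise ValueError("mu must exceed 1")
        if not (1 <= self.l_min <= self.l_max):
            raise ValueError("need 1 <= l_min <= l_max")
        if not (1 <= self.new_territory_min_unvisited <= 8):
            raise ValueError("new_territory_min_unvisited must be in 1..8")
        if self.memory_horizon < 1 or self.doubling_factor < 1:
            raise ValueError("memory_horizon and doubling_factor must be positive")


class LevySampler:
    """Inverse-CDF sampler of the truncated discrete power law.

    P(l) ∝ l^(-mu) on l in [l_min, l_max]; u = 0 maps to l_min and the
    sample is monotone nondecreasing in u.
    """

    def __init__(self, p: LevyParams):
        lengths = np.arange(p.l_min, p.l_max + 1, dtype=np.float64)
        weights = lengths ** (-p.mu)
        self.pmf = weights / weights.sum()
        self.cdf = np.cumsum(self.pmf)
        self.l_min = p.l_min

    def draw(self, u: float) -> int:
        if not (0.0 <= u < 1.0):
            raise ValueError("u must lie in [0, 1)")
        return self.l_min + int(np.searchsorted(self.cdf, u, side="right"))

    def draw_many(self, u: np.ndarray) -> np.ndarray:
        """Vectorised inverse-CDF draws for an array of uniforms."""
        u = np.asarray(u)
        if ((u < 0) | (u >= 1)).any():
            raise ValueError("u must lie in [0, 1)")
        return self.l_min + np.searchsorted(self.cdf, u, side="right")


def draw_levy_length(u: float, p: LevyParams) -> int:
    """Single inverse-CDF draw from the truncated power law."""
    return LevySampler(p).draw(u)


@dataclass
class AgentState:
    """Mutable per-run agent bookkeeping.

    ``last_visit`` maps cells to the global step index of their most recent
    visit; recency is judged against ``global_step`` and the memory
    horizon.  The heading is always one of the eight compass bearings.
    """

    position: CellCoord
    heading_deg: int = 0
    last_visit: dict[tuple[int, int], int] = field(default_factory=dict)
    global_step: int = 0
    walk_index: int = 0

    def visit(self, cell: CellCoord) -> None:
        self.last_visit[(cell.row, cell.col)] = self.global_step
        self.global_step += 1

    def is_recent(self, row: int, col: int, horizon: int) -> bool:
        t = self.last_visit.get((row, col))
        return t is not None and (self.global_step - t) < horizon


def _candidate_neighbors(
    s: AgentState, cs: CostSurface, bearings: Sequence[int]
) -> list[tuple[float, int, int, int]]:
    """(cost, bearing, row, col) for in-bounds non-barrier cells at the bearings."""
    n_rows, n_cols = cs.shape
    barrier = cs.barrier_mask
    cost = cs.cost.values
    r0, c0 = s.position
    out = []
    for b in bearings:
        dr, dc = BEARING_OFFSETS[b]
        r, c = r0 + dr, c0 + dc
        if 0 <= r < n_rows and 0 <= c < n_cols and not barrier[r, c]:
            out.append((cost[r, c], b, r, c))
    return out


def _pick_min_cost(
    cands: list[tuple[float, int, int, int]],
    s: AgentState,
    horizon: int,
    rng: np.random.Generator,
) -> tuple[float, int, int, int] | None:
    """Cheapest non-recent candidate; recency filter dropped if it empties
    the set; exact-cost ties broken uniformly with the run RNG."""
    if not cands:
        return None
    fresh = [c for c in cands if not s.is_recent(c[2], c[3], horizon)]
    pool = fresh if fresh else cands
    best = min(c[0] for c in pool)
    ties = [c for c in pool if c[0] == best]
    if len(ties) == 1:
        return ties[0]
    return ties[rng.integers(len(ties))]


def choose_heading_360(
    s: AgentState, cs: CostSurface, p: LevyParams, rng: np.random.Generator
) -> int | None:
    """Face the cheapest non-recent neighbour, scanning all eight bearings.

    Returns the chosen bearing, or None if every neighbour is a barrier or
    out of bounds (a trapped agent).
    """
    pick = _pick_min_cost(_candidate_neighbors(s, cs, BEARINGS), s, p.memory_horizon, rng)
    return None if pick is None else pick[1]


def cone_neighbors(s: AgentState) -> list[CellCoord]:
    """The cells inside the 100-degree forward cone: relative bearings
    -45, 0, +45 from the heading (never the cells behind the agent)."""
    cells = []
    for rel in (-45, 0, 45):
        b = (s.heading_deg + rel) % 360
        dr, dc = BEARING_OFFSETS[b]
        cells.append(CellCoord(s.position.row + dr, s.position.col + dc))
    return cells


def _cone_bearings(heading: int) -> tuple[int, int, int]:
    return ((heading - 45) % 360, heading, (heading + 45) % 360)


def is_new_territory(
    s: AgentState, p: LevyParams, shape: tuple[int, int] | None = None
) -> bool:
    """True iff at least ``new_territory_min_unvisited`` of the in-bounds
    8-neighbours have not been recently occupied."""
    unvisited = 0
    r0, c0 = s.position
    for b in BEARINGS:
        dr, dc = BEARING_OFFSETS[b]
        r, c = r0 + dr, c0 + dc
        if shape is not None and not (0 <= r < shape[0] and 0 <= c < shape[1]):
            continue
        if not s.is_recent(r, c, p.memory_horizon):
            unvisited += 1
    return unvisited >= p.new_territory_min_unvisited


def do_levy_walk(
    s: AgentState,
    cs: CostSurface,
    p: LevyParams,
    rng: np.random.Generator,
    sampler: LevySampler | None = None,
) -> tuple[list[CellCoord], bool]:
    """Execute one Lévy walk in place; returns (cells visited, trapped flag).

    Order of operations: 360-degree heading choice; length draw; the
    new-territory doubling test; then up to l cone-constrained steps, each
    to the cheapest non-recent candidate, ending early if the cone offers
    no passable cell.  A trapped agent (no candidate in 360 degrees)
    yields an empty walk and the trapped flag.
    """
    sampler = sampler or LevySampler(p)
    heading = choose_heading_360(s, cs, p, rng)
    if heading is None:
        return [], True
    s.heading_deg = heading
    length = sampler.draw(float(rng.random()))
    if is_new_territory(s, p, cs.shape):
        length = min(length * p.doubling_factor, p.l_max * p.doubling_factor)

    path: list[CellCoord] = []
    horizon = p.memory_horizon
    for _ in range(length):
        cands = _candidate_neighbors(s, cs, _cone_bearings(s.heading_deg))
        pick = _pick_min_cost(cands, s, horizon, rng)
        if pick is None:
            break
        _, bearing, r, c = pick
        cell = CellCoord(r, c)
        s.position = cell
        s.heading_deg = bearing
        s.visit(cell)
        path.append(cell)
    s.walk_index += 1
    return path, False


@dataclass
class ScenarioConfig:
    """One simulation run: a world, a start region, a walk budget, a seed.

    ``start_region`` is a shapely polygon in map coordinates; None means
    the whole grid.  The agent starts on a uniformly random non-barrier
    cell whose centre falls inside the region.
    """

    cost_surface: CostSurface
    start_region: BaseGeometry | None = None
    n_walks: int = 400_000
    seed: int = 0
    levy: LevyParams = field(default_factory=LevyParams)
    scenario_id: str = "scenario"

    def __post_init__(self) -> None:
        if self.n_walks < 0:
            raise ValueError("n_walks must be nonnegative")


@dataclass
class Trajectory:
    """Ordered step record of one run.

    Row 0 is the start position (walk_index 0); subsequent rows carry the
    1-based index of the walk that produced them.  Consecutive cells are
    8-adjacent and none is a barrier cell.
    """

    rows: np.ndarray
    cols: np.ndarray
    walk_index: np.ndarray
    cell_size_km: float = 1.0
    origin_xy: tuple[float, float] = (0.0, 0.0)
    seed: int | None = None
    scenario_id: str = "scenario"
    trapped: bool = False

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=np.int64)
        self.cols = np.asarray(self.cols, dtype=np.int64)
        self.walk_index = np.asarray(self.walk_index, dtype=np.int64)
        if not (len(self.rows) == len(self.cols) == len(self.walk_index)) or len(self.rows) == 0:
            raise ValueError("trajectory arrays must be non-empty and equal-length")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def n_steps(self) -> int:
        """Steps actually taken (excludes the start position)."""
        return len(self.rows) - 1

    def xy(self) -> tuple[np.ndarray, np.ndarray]:
        """Cell-centre map coordinates of every recorded position."""
        ox, oy = self.origin_xy
        x = ox + (self.cols + 0.5) * self.cell_size_km
        y = oy + (self._grid_rows - self.rows - 0.5) * self.cell_size_km
        return x, y

    # number of grid rows is needed to map row index to y; carried via the
    # template raster when available, else inferred as max row + 1
    _grid_rows_override: int | None = None

    @property
    def _grid_rows(self) -> int:
        if self._grid_rows_override is not None:
            return self._grid_rows_override
        return int(self.rows.max()) + 1

    def set_grid_rows(self, n_rows: int) -> "Trajectory":
        self._grid_rows_override = int(n_rows)
        return self

    def to_dataframe(self) -> pd.DataFrame:
        x, y = self.xy()
        return pd.DataFrame(
            {
                "run_id": self.scenario_id,
                "walk_index": self.walk_index,
                "step_index": np.arange(len(self.rows)),
                "row": self.rows,
                "col": self.cols,
                "x": x,
                "y": y,
            }
        )

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.to_dataframe().to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        cell_size_km: float = 1.0,
        origin_xy: tuple[float, float] = (0.0, 0.0),
        n_grid_rows: int | None = None,
    ) -> "Trajectory":
        df = pd.read_csv(path)
        traj = cls(
            rows=df["row"].to_numpy(),
            cols=df["col"].to_numpy(),
            walk_index=df["walk_index"].to_numpy(),
            cell_size_km=cell_size_km,
            origin_xy=origin_xy,
            scenario_id=str(df["run_id"].iloc[0]) if len(df) else "scenario",
        )
        if n_grid_rows is not None:
            traj.set_grid_rows(n_grid_rows)
        return traj


def start_cells(cs: CostSurface, region: BaseGeometry | None) -> np.ndarray:
    """(k, 2) array of non-barrier cells whose centres fall in the region."""
    passable = ~cs.barrier_mask
    if region is None:
        rows, cols = np.nonzero(passable)
    else:
        import shapely

        rows, cols = np.nonzero(passable)
        x, y = raster_core.cells_to_xy(cs.cost, rows, cols)
        inside = shapely.contains_xy(region, x, y)
        rows, cols = rows[inside], cols[inside]
    return np.column_stack([rows, cols])


def run_scenario(cfg: ScenarioConfig) -> Trajectory:
    """Run one full scenario and return the complete step record.

    The agent is placed on a uniformly random valid start cell, then
    executes ``n_walks`` Lévy walks.  A permanently trapped agent
    truncates the record (trapped flag set) rather than raising.
    Identical config + seed reproduce the trajectory bit-exactly.
    """
    cs = cfg.cost_surface
    candidates = start_cells(cs, cfg.start_region)
    if len(candidates) == 0:
        raise ValueError("start region contains no passable cell")
    rng = np.random.default_rng(cfg.seed)
    r0, c0 = candidates[rng.integers(len(candidates))]
    state = AgentState(position=CellCoord(int(r0), int(c0)))
    state.visit(state.position)

    sampler = LevySampler(cfg.levy)
    rows = [state.position.row]
    cols = [state.position.col]
    widx = [0]
    trapped = False
    for walk in range(1, cfg.n_walks + 1):
        path, trapped = do_levy_walk(state, cs, cfg.levy, rng, sampler)
        if trapped:
            break
        for cell in path:
            rows.append(cell.row)
            cols.append(cell.col)
            widx.append(walk)
    traj = Trajectory(
        rows=np.array(rows),
        cols=np.array(cols),
        walk_index=np.array(widx),
        cell_size_km=cs.cost.cell_size_km,
        origin_xy=cs.cost.origin_xy,
        seed=cfg.seed,
        scenario_id=cfg.scenario_id,
        trapped=trapped,
    )
    return traj.set_grid_rows(cs.cost.n_rows)
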