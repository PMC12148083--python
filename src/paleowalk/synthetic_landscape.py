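"""Synthetic landscape stacks for testing and calibration.

Generates the layer stack the cost-surface builder expects — elevation
with mountain ranges, annual precipitation with a tunable desert
fraction, steepest-descent rivers with prescribed discharges, and a
northern glacier mask — with the coarse statistical structure of the
continental-scale inputs the dispersal model was designed for: broad
plains, linear ridges, low-cost river corridors, dry interior patches,
and ice along the northern margin.  Everything is deterministic per seed.

These landscapes reproduce structure, not geography: no real drainage
network, climate field, or coastline is emulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .cost_surface import CostSurface, RiverSegment
from .raster_core import GridRaster, cell_to_xy, CellCoord

__all__ = [
    "SynthConfig",
    "make_dem",
    "make_precip",
    "make_rivers",
    "make_glacier_mask",
    "make_water_mask",
    "make_landscape",
    "make_corridor_world",
    "make_uniform_plain",
]


@dataclass
class SynthConfig:
    """Knobs of the synthetic landscape generator.

    Defaults give a 200 km x 200 km world with two mountain ranges, three
    rivers spanning the barrier/crossable width regimes, a 20% desert,
    and ice over the northernmost tenth — enough structure to exercise
    every cost rule while a full simulate-and-analyse cycle stays in the
    seconds range.
    """

    n_rows: int = 200
    n_cols: int = 200
    cell_size_km: float = 1.0
    seed: int = 0
    base_elevation_m: float = 200.0
    n_ranges: int = 2
    range_height_m: float = 2000.0
    range_width_cells: float = 6.0
    noise_sd_m: float = 20.0
    n_rivers: int = 3
    river_discharges_m3s: list[float] = field(default_factory=lambda: [30_000.0, 5_000.0, 200.0])
    desert_fraction: float = 0.2
    glacier_lat_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1 or self.cell_size_km <= 0:
            raise ValueError("grid dimensions and cell size must be positive")
        if not (0.0 <= self.desert_fraction <= 1.0):
            raise ValueError("desert_fraction must lie in [0, 1]")
        if not (0.0 <= self.glacier_lat_fraction <= 1.0):
            raise ValueError("glacier_lat_fraction must lie in [0, 1]")
        if self.n_ranges < 0 or self.n_rivers < 0:
            raise ValueError("counts must be nonnegative")


def _rng(cfg: SynthConfig, salt: int) -> np.random.Generator:
    # independent substreams per layer so layers do not shift when another
    # layer's parameters change
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, salt]))


def make_dem(cfg: SynthConfig) -> GridRaster:
    """Elevation: smooth base + Gaussian-profile linear ridges + noise."""
    rng = _rng(cfg, 1)
    rr, cc = np.mgrid[0 : cfg.n_rows, 0 : cfg.n_cols].astype(np.float64)
    z = np.full(cfg.n_rows * cfg.n_cols, cfg.base_elevation_m).reshape(cfg.n_rows, cfg.n_cols)
    for _ in range(cfg.n_ranges):
        # a ridge is a random line through the grid with a Gaussian cross-profile
        r0 = rng.uniform(0, cfg.n_rows)
        c0 = rng.uniform(0, cfg.n_cols)
        theta = rng.uniform(0, np.pi)
        nx, ny = np.sin(theta), np.cos(theta)  # unit normal of the ridge line
        d = (rr - r0) * nx + (cc - c0) * ny
        z = z + cfg.range_height_m * np.exp(-0.5 * (d / cfg.range_width_cells) ** 2)
    if cfg.noise_sd_m > 0:
        z = z + ndimage.gaussian_filter(
            rng.normal(0.0, cfg.noise_sd_m, z.shape), sigma=1.0
        )
    return GridRaster(z, cell_size_km=cfg.cell_size_km)


def make_precip(cfg: SynthConfig, dem: GridRaster | None = None) -> GridRaster:
    """Annual precipitation (mm/yr) with ~``desert_fraction`` of cells < 250 mm.

    A smooth west-to-east gradient plus filtered noise, affinely rescaled
    so the desert threshold falls at the configured quantile.
    """
    rng = _rng(cfg, 2)
    _, cc = np.mgrid[0 : cfg.n_rows, 0 : cfg.n_cols].astype(np.float64)
    raw = cc / max(cfg.n_cols - 1, 1) + ndimage.gaussian_filter(
        rng.normal(0.0, 1.0, (cfg.n_rows, cfg.n_cols)), sigma=max(cfg.n_cols / 20.0, 1.0)
    )
    lo, hi = raw.min(), raw.max()
    span = hi - lo if hi > lo else 1.0
    unit = (raw - lo) / span  # in [0, 1]
    threshold = 250.0
    if cfg.desert_fraction <= 0.0:
        precip = threshold + unit * 600.0
    elif cfg.desert_fraction >= 1.0:
        precip = unit * (threshold - 1.0)
    else:
        q = np.quantile(unit, cfg.desert_fraction)
        q = min(max(q, 1e-9), 1 - 1e-9)
        # piecewise-affine: quantile q maps to the threshold, extremes to 50 / 850 mm
        precip = np.where(
            unit < q,
            50.0 + (unit / q) * (threshold - 50.0),
            threshold + (unit - q) / (1 - q) * 600.0,
        )
    return GridRaster(precip, cell_size_km=cfg.cell_size_km)


def make_rivers(cfg: SynthConfig, dem: GridRaster) -> list[RiverSegment]:
    """Rivers as steepest-descent polylines from random high cells.

    Sources are drawn without replacement from the top elevation decile;
    each course follows the steepest downhill 8-neighbour until it reaches
    the grid edge or a local minimum, so elevations are strictly
    decreasing along the course.  Discharges are assigned in the
    configured order (cycled if fewer values than rivers are given).
    """
    if cfg.n_rivers == 0:
        return []
    if not cfg.river_discharges_m3s:
        raise ValueError("river_discharges_m3s must be non-empty when n_rivers > 0")
    rng = _rng(cfg, 3)
    z = dem.values
    cutoff = np.quantile(z, 0.9)
    sources = np.column_stack(np.nonzero(z >= cutoff))
    if len(sources) < cfg.n_rivers:
        raise ValueError(
            f"only {len(sources)} distinct high-ground sources for {cfg.n_rivers} rivers"
        )
    picks = rng.choice(len(sources), size=cfg.n_rivers, replace=False)
    offsets = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]
    rivers = []
    for i, pick in enumerate(picks):
        r, c = map(int, sources[pick])
        path = [CellCoord(r, c)]
        visited = {(r, c)}
        while True:
            best = None
            for dr, dc in offsets:
                nr, nc = r + dr, c + dc
                if not (0 <= nr < cfg.n_rows and 0 <= nc < cfg.n_cols):
                    best = None  # reached the edge; stop the course here
                    break
                if (nr, nc) in visited:
                    continue
                if z[nr, nc] < z[r, c] and (best is None or z[nr, nc] < z[best]):
                    best = (nr, nc)
            else:
                if best is None:
                    break  # local minimum
                r, c = best
                visited.add((r, c))
                path.append(CellCoord(r, c))
                continue
            break
        if len(path) < 2:
            path.append(CellCoord(min(r + 1, cfg.n_rows - 1), c))
        discharge = cfg.river_discharges_m3s[i % len(cfg.river_discharges_m3s)]
        xy = [cell_to_xy(dem, cell) for cell in path]
        rivers.append(RiverSegment(xy=xy, discharge_m3s=float(discharge)))
    return rivers


def make_glacier_mask(cfg: SynthConfig) -> GridRaster:
    """Ice over the top ``glacier_lat_fraction`` of rows (northern margin)."""
    mask = np.zeros((cfg.n_rows, cfg.n_cols))
    n_ice = int(round(cfg.glacier_lat_fraction * cfg.n_rows))
    mask[:n_ice, :] = 1.0
    return GridRaster(mask, cell_size_km=cfg.cell_size_km)


def make_water_mask(cfg: SynthConfig) -> GridRaster:
    """Lake/ocean mask; the synthetic world is landlocked (all False)."""
    return GridRaster(np.zeros((cfg.n_rows, cfg.n_cols)), cell_size_km=cfg.cell_size_km)


def make_landscape(cfg: SynthConfig) -> dict:
    """Full layer stack ready for the cost-surface builder."""
    dem = make_dem(cfg)
    return {
        "dem": dem,
        "precip": make_precip(cfg, dem),
        "rivers": make_rivers(cfg, dem),
        "glacier_mask": make_glacier_mask(cfg),
        "water_mask": make_water_mask(cfg),
    }


def make_corridor_world(
    length_cells: int,
    corridor_cost: float = 1.0,
    offcorridor_cost: float = 1.74,
    cell_size_km: float = 1.0,
) -> CostSurface:
    """Uniform plain with a 1-cell-wide low-cost corridor spanning west to
    east along the middle row; no barriers.  The fixture behind the
    corridor-emergence property: agents should over-use the cheap line the
    way simulated foragers over-use river valleys."""
    if length_cells < 3:
        raise ValueError("corridor world needs at least 3 cells per side")
    if corridor_cost >= offcorridor_cost:
        raise ValueError("corridor must be cheaper than the surrounding plain")
    cost = np.full((length_cells, length_cells), float(offcorridor_cost))
    cost[length_cells // 2, :] = float(corridor_cost)
    return CostSurface.from_arrays(cost, cell_size_km=cell_size_km)


def make_uniform_plain(
    n_cells: int, cost: float = 1.0, cell_size_km: float = 1.0
) -> CostSurface:
    """Open uniform-cost plain with no barriers (calibration fixture)."""
    return CostSurface.from_arrays(
        np.full((n_cells, n_cells), float(cost)), cell_size_km=cell_size_km
    )
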