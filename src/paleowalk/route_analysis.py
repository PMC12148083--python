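"""Route statistics: success classification, straight segments, occupancy
frequency, redundancy zones, and arrival-time estimation.

A run is *successful* when any of its steps comes within a buffer radius
(default 500 km) of a target site; for failed runs the residual distance
to the buffer edge (distance to the nearest site minus the radius) is the
headline miss statistic.  Long-distance linear movements are read off the
trajectory as maximal runs of at least five steps with an unchanging
movement bearing — since steps land on the eight compass bearings, "angle
does not change" is an exact integer comparison.  Arrival time converts
the step count to years by dividing the distance walked (steps x cell
size) by an ethnographically derived annual travel distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster_core import GridRaster
from .walker_engine import Trajectory, step_bearing

__all__ = [
    "TargetSpec",
    "RouteMetrics",
    "StraightSegment",
    "classify_success",
    "straight_segments",
    "occupancy_frequency",
    "redundancy_zones",
    "arrival_years",
]


@dataclass
class TargetSpec:
    """Target sites and the success-buffer radius around them."""

    site_points: list[tuple[float, float]]
    buffer_km: float = 500.0

    def __post_init__(self) -> None:
        if not self.site_points:
            raise ValueError("need at least one target site")
        if self.buffer_km <= 0:
            raise ValueError("buffer_km must be positive")


@dataclass
class StraightSegment:
    """A maximal run of same-bearing steps.

    ``start_index`` is the index (into the trajectory's position list) of
    the position from which the first step of the run departs;
    ``net_distance_km`` counts every step as one cell size, diagonal or
    not.
    """

    start_index: int
    length_steps: int
    bearing_deg: int
    net_distance_km: float


@dataclass
class RouteMetrics:
    """Per-run route summary."""

    success: bool
    min_distance_to_buffer_km: float
    endpoint_distance_to_buffer_km: float
    n_steps_to_target: int | None
    straight_segments: list[StraightSegment]
    est_years: float | None


def _site_distances(traj: Trajectory, tgt: TargetSpec) -> np.ndarray:
    """Distance from every recorded position to its nearest target site."""
    x, y = traj.xy()
    best = np.full(len(x), np.inf)
    for sx, sy in tgt.site_points:
        np.minimum(best, np.hypot(x - sx, y - sy), out=best)
    return best


def classify_success(
    t: Trajectory,
    tgt: TargetSpec,
    annual_km: float | None = None,
    min_segment_len: int = 5,
) -> RouteMetrics:
    """Classify a run against the target buffer and fill in all metrics.

    Success means some position lies within ``buffer_km`` (planar
    Euclidean) of a site; ``n_steps_to_target`` counts the steps taken to
    the first such position (0 if the start is already inside).  When
    ``annual_km`` is given, successful runs also get an arrival-time
    estimate.
    """
    if len(t) == 0:
        raise ValueError("empty trajectory")
    dist = _site_distances(t, tgt)
    inside = dist <= tgt.buffer_km
    success = bool(inside.any())
    n_steps_to_target = int(np.argmax(inside)) if success else None
    est = None
    if success and annual_km is not None:
        est = arrival_years(n_steps_to_target, annual_km, t.cell_size_km)
    return RouteMetrics(
        success=success,
        min_distance_to_buffer_km=float(max(dist.min() - tgt.buffer_km, 0.0)),
        endpoint_distance_to_buffer_km=float(max(dist[-1] - tgt.buffer_km, 0.0)),
        n_steps_to_target=n_steps_to_target,
        straight_segments=straight_segments(t, min_segment_len),
        est_years=est,
    )


def straight_segments(t: Trajectory, min_len: int = 5) -> list[StraightSegment]:
    """Maximal runs of consecutive same-bearing steps, length >= min_len.

    Segments never overlap, and extending one by a step on either side
    would change its bearing (or run off the trajectory).
    """
    n_steps = len(t) - 1
    if n_steps < min_len:
        return []
    dr = np.diff(t.rows)
    dc = np.diff(t.cols)
    bearings = np.array([step_bearing(int(a), int(b)) for a, b in zip(dr, dc)])
    # run boundaries where the bearing changes
    change = np.nonzero(bearings[1:] != bearings[:-1])[0] + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [n_steps]])
    out = []
    for s, e in zip(starts, ends):
        if e - s >= min_len:
            out.append(
                StraightSegment(
                    start_index=int(s),
                    length_steps=int(e - s),
                    bearing_deg=int(bearings[s]),
                    net_distance_km=float((e - s) * t.cell_size_km),
                )
            )
    return out


def occupancy_frequency(trajs: list[Trajectory], template: GridRaster) -> GridRaster:
    """Per-cell visit count across runs divided by the number of runs.

    Every recorded position counts, including the start and repeat visits,
    so sum(values) * n_runs equals the total number of recorded positions.
    """
    if not trajs:
        raise ValueError("need at least one trajectory")
    counts = np.zeros(template.shape, dtype=np.float64)
    for t in trajs:
        if t.rows.max() >= template.n_rows or t.cols.max() >= template.n_cols:
            raise ValueError("trajectory does not fit the template grid")
        np.add.at(counts, (t.rows, t.cols), 1.0)
    return template.copy_with(counts / len(trajs))


def redundancy_zones(freq: GridRaster, rule: str = "within_1sd") -> GridRaster:
    """Mask of redundantly used cells, by occupancy-frequency statistics.

    Statistics (mean, sd) are computed over the visited (nonzero) cells
    only.  ``within_1sd`` marks visited cells with |f - mean| <= sd;
    ``above_1sd`` marks cells with f > mean + sd.  An all-zero frequency
    field gives an empty mask.
    """
    if rule not in ("within_1sd", "above_1sd"):
        raise ValueError(f"unknown rule {rule!r}")
    f = freq.values
    visited = f > 0
    mask = np.zeros(freq.shape, dtype=bool)
    if visited.any():
        mean = f[visited].mean()
        sd = f[visited].std()
        if rule == "within_1sd":
            mask = visited & (np.abs(f - mean) <= sd)
        else:
            mask = visited & (f > mean + sd)
    return freq.copy_with(mask.astype(np.float64))


def arrival_years(n_steps: int, annual_km: float, cell_size_km: float = 1.0) -> float:
    """Years to cover ``n_steps`` steps at an annual travel distance.

    Each step covers one cell size (1 km nominally), so the estimate is
    simply n_steps * cell_size_km / annual_km.
    """
    if annual_km <= 0:
        raise ValueError("annual_km must be positive")
    if n_steps < 0:
        raise ValueError("n_steps must be nonnegative")
    return n_steps * cell_size_km / annual_km
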