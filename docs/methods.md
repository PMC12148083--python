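# Methods

`paleowalk` simulates long-distance dispersal as an agent-based
least-cost-path (AB-LCP) process: a single agent performs cost-minimising
Lévy walks over a static raster of traversal costs, with no destination
and no global knowledge of the landscape.  Routes — and in particular the
river-corridor routes the approach is known for — emerge entirely from
local decisions.  This note documents the model, its parameters, the
numerical choices, and what the synthetic test landscapes do and do not
establish.

## The movement model

The world is a square-cell raster (nominally 1 km cells) of dimensionless
traversal costs plus a boolean barrier mask.  Time advances in *walks*;
each walk is:

1. **360° evaluation.** The agent inspects its eight neighbours and faces
   the cheapest one it has not *recently occupied* (visited within the
   last `memory_horizon` global steps).  If every candidate is recent,
   the recency filter is dropped rather than halting the agent; if every
   neighbour is a barrier or off-grid, the agent is trapped and the run
   ends (truncated, not an error).
2. **Length draw.** The walk length `l` is drawn from the truncated
   discrete power law `P(l) ∝ l^(−μ)` on `[l_min, l_max]` by inverse
   CDF.
3. **New-territory doubling.** If at least
   `new_territory_min_unvisited` of the agent's in-bounds neighbours are
   not recent (default 5 of 8, "most"), `l` is doubled, capped at
   `l_max × doubling_factor`.  This colonisation rule fires routinely at
   an expanding front and rarely inside well-trodden ground, and is what
   produces the occasional long-distance push.
4. **Cone-constrained stepping.** For each of the `l` steps the agent
   considers only the three cells at relative bearings −45°/0°/+45° from
   its heading (a 100° forward cone — never the cells behind it), moves
   to the cheapest non-recent passable one, and updates its heading to
   the direction moved.  The walk ends early if the cone offers no
   passable cell.

Exact-cost ties are broken uniformly at random.  All randomness — start
cell, length draws, tie-breaks — comes from one `numpy` generator seeded
per run, consumed in the order just described, so a run is
bit-reproducible from `(inputs, seed)`.  Cost comparisons use exact
ordering on the stored float values; no tolerance is applied, which keeps
the argmin well-defined and the runs portable.

Every step covers one cell size (1 km), diagonals included: the model's
step counts are read directly as kilometres, which is also how step
counts convert to years below.  Distances are planar Euclidean in map
units throughout; inputs are assumed to be already-projected square-km
rasters and no geodesic correction is applied.

### Movement parameters

| parameter | default | meaning |
|---|---|---|
| `mu` | 2.93 | power-law exponent of walk length |
| `l_min`, `l_max` | 1, 100 | truncation bounds (steps) |
| `memory_horizon` | 10 000 steps | recency window for "recently occupied" |
| `new_territory_min_unvisited` | 5 of 8 | doubling trigger |
| `doubling_factor` | 2 | length multiplier in new territory |

The defaults are calibrated, not asserted: the reference behaviour is an
average of roughly 830 000 steps per 400 000 walks (≈ 2.075 steps per
walk).  With integer-valued lengths there is no scale parameter separate
from the exponent, so `mu` is the calibration knob: bisection on an open
uniform 300×300 plain (10 000 walks per run, 10 seeds;
`scripts/calibrate_levy.py`) gives `mu = 2.93`, which reproduces the
target mean to within ±0.01 under those conditions.  The memory horizon
is a modelling necessity rather than a published value — some finite
window is required for the recency fallback to clear culs-de-sac — and
10 000 steps keeps the agent self-avoiding on the scale of a regional
excursion while letting it re-cross old ground on the scale of a run.
Recency is updated per step, not per walk.

## The cost surface

The base cost is walking energetics as a function of terrain slope: the
Llobera–Sluckin quartic in gradient,

    C(m) = 2.635 + 17.37 m + 42.37 m² − 21.43 m³ + 14.93 m⁴,

normalised so flat ground costs 1.  The penalty system is anchored on a
single hard constant: moving from flat ground to a 15° slope costs 74%
more.  The raw quartic under the tan-gradient convention gives a ~3.79×
ratio at 15°, so the gradient axis is rescaled once by a constant
(`GRADIENT_SCALE ≈ 0.3447`, solved at import by Brent's method to
~1e-14) such that `C(k·tan 15°)/C(0) = 1.74` exactly.  This preserves
the quartic's shape — continuity, strict monotonicity on ascent — while
matching the anchor.  The function is applied to the slope magnitude
(symmetric in sign), so cost is never below its flat value.

Slope itself comes from Horn's 3×3 finite-difference stencil on the DEM,
in degrees; edges are handled by replication and nodata cells are filled
from their nearest valid neighbour for the stencil only (the cells
themselves stay nodata, and become barriers).

On this base, land-cover penalties stack **multiplicatively** (a 74%
increase is naturally a ×1.74 factor; additive stacking is available via
`CostConfig.stacking`):

- **Desert:** cells with annual precipitation strictly below 250 mm cost
  ×1.74.  The comparison is strict — a cell at exactly 250 mm is not
  penalised.
- **Narrow rivers:** river width is estimated from long-term mean
  discharge by downstream hydraulic geometry, `w = a·Q^b` with defaults
  `a = 7.2`, `b = 0.5` (standard width–discharge scaling; both
  configurable).  Rivers narrower than one cell (1000 m) are crossable
  at ×1.74; rivers at least a cell wide are barriers.
- A cell that is both desert and narrow-river costs 1.74² ≈ 3.03; the
  compounding rule is a documented package choice.

Barriers — ocean/lake mask, glacier mask, wide rivers, flooded
paleolakes, nodata — always win over any cost modifier; barrier cells
carry the nodata sentinel in the cost raster and are never offered to
the agent.  Paleolakes are produced by flooding the DEM from configured
seed cells up to configured water levels using a 4-connected fill
(4-connectivity prevents water leaking through diagonal land gaps);
lake levels and seeds are config data, not code.

River polylines are rasterised by an exact supercover grid traversal
(parametric crossings of the grid lines), so a wide river's trace is
gap-free and agents cannot slip through a diagonal crack.

## Route analysis

- **Success:** a run succeeds if any recorded position lies within a
  buffer radius (default 500 km) of any target site — equivalently, a
  union-of-discs buffer around the sites.  For failures the residual is
  the distance from the nearest approach (or the endpoint) to the buffer
  edge, i.e. distance-to-site minus radius.
- **Straight segments:** maximal runs of ≥ 5 consecutive steps with an
  identical movement bearing.  Step bearings are multiples of 45°, so
  "angle does not change" is an exact integer comparison with no
  floating-point tolerance; net distance is steps × cell size, per the
  global step-distance convention.
- **Occupancy frequency:** per-cell visit counts across runs divided by
  the number of runs.  Each step-visit counts (revisits count twice),
  which preserves the conservation identity `sum(freq) × n_runs = total
  recorded positions` and keeps redundancy information.
- **Redundancy zones:** statistics (mean, SD) over visited cells only.
  Two rules ship because the intended reading of "within 1 SD of the
  mean" is ambiguous between literal band membership and high-use cells:
  `within_1sd` (|f − mean| ≤ SD, the default, following the letter) and
  `above_1sd` (f > mean + SD).
- **Arrival time:** `years = steps × cell_size / annual_km`, where
  `annual_km` is an ethnographically derived annual travel distance per
  scenario.  The two rates shipped as illustrative defaults in examples
  (579.0 and 696.5 km/yr) are back-derived from published step/year
  pairs, not independently sourced, and the conversion is an
  internal-consistency check rather than a prediction.

## Synthetic landscapes

The generator emits the layer stack the cost builder consumes — DEM with
Gaussian-profile mountain ridges and filtered noise, a precipitation
field quantile-scaled to a target desert fraction, steepest-descent
rivers with prescribed discharges, a northern glacier band — plus two
analytic fixtures: an open uniform plain (the calibration condition) and
a plain bisected by a one-cell-wide cheap corridor (costs 1.0 vs 1.74),
which agents demonstrably over-use relative to its area share: the
mechanism behind river-valley routes.

These worlds reproduce *structure*, not geography: there is no real
drainage network, no climate model, no coastline, and no
glacio-isostatic or drainage-rerouting dynamics.  Passing tests
therefore establish that the machinery implements its rules exactly and
that corridor-following emerges from them — not that any particular
real-world route would be reproduced.  Grids are kept small (≤ 500×500,
mostly 40–300) so full simulate-and-analyse cycles run in seconds; all
sizes are config knobs.

## Scope and limitations

- One agent per run; no demography, resource depletion, agent
  interaction, or within-run landscape change (cost surfaces are static).
- No reprojection or geodesic handling; inputs must share a projected
  square-cell grid.
- The experiment runner's replicate seeds are `base_seed + replicate`,
  recorded in a manifest with a config hash, which suffices to reproduce
  every output byte-for-byte — but published run sets with unreported
  seeds cannot be reproduced run-for-run, and no claim of that kind is
  made.
- Trapped agents (all eight neighbours impassable) end a run early with
  a flag; on realistic barrier densities this is rare but it is the
  correct outcome for, e.g., an island start region.
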