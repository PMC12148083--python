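"""Calibrate the Lévy exponent against the mean-steps-per-walk target.

The published model averages roughly 830,000 steps per 400,000 walks
(about 2.075 steps per walk).  With the walk-length truncation, memory
horizon, and new-territory doubling fixed at their defaults, the exponent
mu is the single free scale of the step budget; this script bisects mu so
that the mean steps-per-walk on an open uniform plain hits the target,
using scaled-down runs (10,000 walks on a 300x300 plain).

Usage: python scripts/calibrate_levy.py [--target 2.075] [--seeds 10]
The result is what ships as ``LevyParams.mu``.
"""

from __future__ import annotations

import argparse
import dataclasses

import numpy as np

from paleowalk.synthetic_landscape import make_uniform_plain
from paleowalk.walker_engine import LevyParams, ScenarioConfig, run_scenario


def mean_steps_per_walk(mu: float, n_seeds: int, n_walks: int = 10_000, plain: int = 300) -> float:
    base = dataclasses.replace(LevyParams(), mu=mu)
    vals = []
    for seed in range(n_seeds):
        cs = make_uniform_plain(plain)
        traj = run_scenario(
            ScenarioConfig(cost_surface=cs, n_walks=n_walks, seed=seed, levy=base)
        )
        vals.append(traj.n_steps / n_walks)
    return float(np.mean(vals))


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--target", type=float, default=2.075)
    ap.add_argument("--seeds", type=int, default=10)
    ap.add_argument("--tol", type=float, default=0.02)
    args = ap.parse_args()

    lo, hi = 2.0, 5.0  # mean steps decreases with mu over this bracket
    f_lo = mean_steps_per_walk(lo, args.seeds)
    f_hi = mean_steps_per_walk(hi, args.seeds)
    print(f"bracket: mu={lo} -> {f_lo:.3f}, mu={hi} -> {f_hi:.3f}")
    if not (f_hi < args.target < f_lo):
        raise SystemExit("target outside bracket; widen [lo, hi]")
    while hi - lo > 1e-2:
        mid = 0.5 * (lo + hi)
        f_mid = mean_steps_per_walk(mid, args.seeds)
        print(f"mu={mid:.4f} -> {f_mid:.4f}")
        if abs(f_mid - args.target) < args.tol:
            lo = hi = mid
            break
        if f_mid > args.target:
            lo = mid
        else:
            hi = mid
    mu = round(0.5 * (lo + hi), 2)
    print(f"calibrated mu = {mu} (achieves {mean_steps_per_walk(mu, args.seeds):.4f})")


if __name__ == "__main__":
    main()
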