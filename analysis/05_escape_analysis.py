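#!/usr/bin/env python
"""Escape analysis: when does a compensatory mutation rescue the clone?

Triggers compensation at increasing colony radii r* in agent-based
ensembles and measures (per r*) the linear growth slope of the mean
compensated width, the expansion Δr_escape needed to reach the 6-cell
escape width, the escape probability P_escape within the horizon, the
mutation probability P_mutate(w̄(r*)) at μ = 0.1 per step, and the product
P_total = P_escape · P_mutate.  Later triggers inflate less, so the slope
and P_escape decrease with r* while P_mutate saturates — the origin of the
broad optimum in P_total.  Writes results/escape.csv.
"""

import pathlib

import pandas as pd

from isbalance.abm import ABMConfig, run_abm
from isbalance.estimators import escape_analysis

ROOT = pathlib.Path(__file__).resolve().parents[1] / "results"
ROOT.mkdir(parents=True, exist_ok=True)

R_STARS = (110.0, 170.0, 230.0)
N_SEEDS = 3


def main() -> None:
    rows = []
    for r_star in R_STARS:
        tables = []
        for seed in range(N_SEEDS):
            cfg = ABMConfig(r_final=r_star + 310.0, ring_radius=90.0,
                            seed=seed, mutation_mode="triggered", r_star=r_star)
            table, _ = run_abm(cfg)
            tables.append(table)
        ea = escape_analysis(tables, r_star, mu_per_step=0.1,
                             horizon=300.0, cell_diameter=12.0)
        rows.append({
            "r_star": r_star, "slope": ea.slope, "dr_escape": ea.dr_escape,
            "p_escape": ea.p_escape, "p_mutate": ea.p_mutate,
            "p_total": ea.p_total, "n_clones": ea.n_clones,
        })
        print(f"r* = {r_star:5.0f}: slope {ea.slope:6.3f} μm/μm, "
              f"Δr_escape {ea.dr_escape:7.0f} μm, P_escape {ea.p_escape:.2f}, "
              f"P_mutate {ea.p_mutate:.2f}, P_total {ea.p_total:.3f} "
              f"({ea.n_clones} clones)")
    frame = pd.DataFrame(rows)
    frame.to_csv(ROOT / "escape.csv", index=False)
    if frame["slope"].is_monotonic_decreasing:
        print("mean compensated width growth slows with later triggers, "
              "as expected from weaker inflation at larger radii")


if __name__ == "__main__":
    main()
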