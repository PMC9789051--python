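# isbalance

Simulation and analysis toolkit for **evolutionary rescue in radially
expanding dense populations** — how costly drug-resistant clones, doomed to
extinction by purifying selection, persist at the front of a growing
microbial colony or 2D tumor long enough to pick up a compensatory mutation
and eventually cause treatment failure.

## The science in one page

A resistant clone with fitness cost *s* occupies an arc of width *w* at the
front of a colony of radius *r*. Two forces change its width per μm of
radial growth:

- **inflation** — the front stretches, ∂ᵣw_inf = w/r;
- **selection** — each of the clone's two boundaries drifts into the
  less-fit side with the equal-time bias b(s) = √(|s|(2+s)), shrinking the
  clone at 2·b.

With a *constant* s, the balance point w = 2·b·r is unstable: narrow clones
die, wide clones take over. In dense populations, however, mechanical
coupling suppresses selection for narrow clones. Using the minimal logistic
form

    s_eff(w) = s₀ · 2 / (1 + e^(w_c/w)),

which vanishes faster than inflation as w → 0, the balance becomes **stable**
(*inflation–selection balance*): uncompensated clones sit at a quasi-constant
equilibrium width (tens of μm for s₀ = 0.013, w_c = 280 μm), survive far
longer than the constant-cost null model predicts, and therefore have
drastically more opportunity to acquire a compensatory mutation (rate μ per
cell per μm of growth) that restores wild-type fitness.

The package implements:

- `isbalance.rw` — clone boundaries as selection-biased 1D random walks in
  angular space (per-step arc noise variance 4·D·dr, D = 0.23), with
  annihilation on crossing and compensatory nucleation; three selection
  modes: full-cost null, constant-rescaled, width-dependent;
- `isbalance.abm` — a reduced off-lattice agent-based colony (nutrient
  diffusion with circular Dirichlet boundary, peripheral growth layer,
  overdamped polynomial repulsion, stochastic or radius-triggered
  compensation);
- `isbalance.stats` — lineage tracking, survival curves P_surv(r) = n/n₀
  with Poisson errors, rescue efficacy E = 1 − P^no-rescue/P^with-rescue
  with error propagation and the window of inefficacy, treatment-failure
  summaries, width series and log-transformed KDE width distributions;
- `isbalance.estimators` — mutation rate from front-frequency decay
  (orthogonal distance regression), fitness cost from sector opening angles,
  P_mutate = 1 − (1−μ)^w, and the escape analysis
  P_total = P_escape · P_mutate;
- `isbalance.synth` — synthetic clone-trajectory tables with segmentation-style
  noise (angular jitter, pixel quantization) and known ground truth.

## Worked example

```python
import numpy as np
from isbalance import RWConfig, run_simulation, survival_curve, efficacy, width_series

base = dict(n0=10_000, r0=1500.0, r_final=7500.0, snapshot_dr=750.0)
with_rescue = run_simulation(RWConfig(mu=1e-4, seed=11, **base))
no_rescue   = run_simulation(RWConfig(mu=0.0,  seed=12, **base))

grid = np.arange(1500.0, 7501.0, 750.0)
e = efficacy(survival_curve(no_rescue, grid), survival_curve(with_rescue, grid))
print(round(e.e[-1], 3), round(e.window_of_inefficacy))
_, (w_eq, spread) = width_series(with_rescue, "R-", plateau_range=(4500, 7500))
print(round(w_eq, 1), round(spread, 1))
```

prints

```
0.576 3000
45.3 15.9
```

meaning: over nine simulated days of expansion (radius 1500 → 7500 μm) the
rescue efficacy is still zero within errors up to r ≈ 3000 μm (the window of
inefficacy — treating before this point gains nothing from blocking
compensation) and reaches **0.58** at the end, i.e. ~58% of surviving
lineages owe their survival to a compensatory mutation; uncompensated clones
plateau at a median width of **45 ± 16 μm** instead of dying out, matching
the colony-scale observation of 50 ± 17 μm.

The numbered scripts under `analysis/` run the full pipeline (scenario
comparison, width equilibrium and its r₀ sensitivity, survival/efficacy and
treatment failure, one agent-based colony, escape analysis) and write their
tables under `results/`.

A thin CLI mirrors the library:

```bash
isbalance simulate-rw --config cfg.yaml --out table.csv --seed 1
isbalance analyze --table table.csv --out report.json --treatment-r 4500
isbalance synth trajectories --out synth --seed 1
isbalance estimate mu --freq synth_freq.csv
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from fresh paired simulations at n₀ = 10⁴ (width-dependent
selection, s₀ = 0.013, w_c = 280 μm, D = 0.23, initial widths N(20, 5) μm,
nine daily snapshots to 7500 μm): the end-of-expansion rescue efficacy
(`t2`, paired μ = 10⁻⁴ μm⁻¹ vs negligible-mutation runs) and the
fold-increase of the compensation-and-survival probability P_comp over the
full-cost null model at the same mutation rate (`t3`). Runtime ≈ 30 s.
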