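# Methods

This note records the models, the parameter choices that matter, the
numerical decisions, and what the synthetic data do and do not establish.

## 1. Boundary random-walk model (`isbalance.rw`)

### Model

Each resistant clone on the expanding front is a contiguous set of typed
segments (uncompensated `R-`, compensated `R+`) delimited by boundaries that
perform independent 1D random walks in angular space. Per radial step `dr`
a boundary at angle Φ on a front of radius r receives an arc-length
displacement η ~ N(b_eff·dr, 4·D·dr) and moves by Φ ← Φ + η/(r + dr/2).
Widths are arc lengths, w = r·Δθ; radial inflation therefore needs no
explicit term.

**Bias convention.** The equal-time construction gives each *walker* the
lateral bias b(s) = √(|s|(2+s)) per μm of radial growth, directed into the
less-fit side. Consequences used throughout:

- a slower sector flanked by two fitter neighbors shrinks deterministically
  at ∂ᵣw_sel = 2·b(s);
- a faster sector's full opening angle grows as φ(r) = φ₀ + 2·b·ln(r/r₀),
  which is exactly the form the opening-angle fitness estimator fits — the
  simulator and the assay share one convention (checked by a cross-model
  recovery test);
- in the D = 0 limit a single boundary obeys x/r = x₀/r₀ − b·ln(r/r₀) and a
  sector obeys w/r = w₀/r₀ − 2·b·ln(r/r₀), both reproduced by the engine to
  < 10⁻⁶ relative error.

One also finds the one-b form ∂ᵣw_sel = b quoted for the sector width in
parts of the literature; we adopted the per-walker convention because only
it is simultaneously consistent with the equal-time sector-expansion law
used for fitness estimation and with the measured equilibrium width
(≈ 46 μm vs the observed 50 ± 17 μm at the calibrated parameters; the
one-b convention gives ≈ 60 μm and far too little late-time extinction).

**Width-dependent selection.** s_eff(w) = s₀·2/(1 + e^(w_c/w)), evaluated on
the width of the adjacent R- segment from the previous step (R+/R-
boundaries included; WT/R+ boundaries are neutral). s_eff vanishes
superexponentially at small w, so the inflation term w/r always wins at
small widths and the deterministic drift ∂ᵣw = w/r − 2·b(s_eff(w)) has a
stable root w*(r) (≈ 39 μm at r = 3000 μm, slowly decreasing with r). The
stochastic plateau median sits slightly above w* because extinction removes
the lower tail.

**Annihilation.** Boundaries of one clone annihilate when they cross; the
enclosed segment is extinct at that radius. Same-type flanks merge;
different-type flanks get a single boundary at the midpoint of the crossed
pair. Simultaneous crossings resolve deepest-first with rechecks.
Clones are *independent and non-interacting* (walkers of different lineages
never annihilate): with the canonical ensemble (10⁴ clones of ~20 μm on a
9.4 mm circumference) the clones could not coexist on one physical circle
anyway, so angular placement is bookkeeping; `require_packing=True` enables
the physical non-overlapping layout for small fronts (and errors when
infeasible).

**Compensation.** Per step each R- segment of width w nucleates with
probability 1 − exp(−μ·(w/cell_diameter)·dr) — the per-cell kinetics that
underlie the frequency-decay law used to calibrate μ experimentally — and a
one-cell-diameter R+ nucleus is inserted at a uniform position (segments
narrower than one cell convert entirely). A `per_clone_constant_rate` mode
exists for sensitivity analysis. The nucleation rule is a modeling choice;
the original description leaves it open.

### Parameters (defaults)

| parameter | value | meaning / provenance |
|---|---|---|
| s₀ | 0.013 | fitness cost of resistance (colony assay) |
| w_c | 280 μm | critical width of the logistic s_eff (calibrated to the width plateau) |
| D | 0.23 | genetic drift; per-boundary arc variance per step = 4·D·dr, dr in μm |
| μ | 10⁻⁴ μm⁻¹ | compensatory rate per cell per μm of radial growth |
| init widths | N(20, 5) μm, truncated > 0 | inoculated clone sizes |
| r₀ → r_final | 1500 → 7500 μm | day-1 to day-9 radii, nine snapshots of 750 μm |
| cell_diameter | 12 μm | from the agent-based scale (39.24 μm ≡ 3.27 cells) |
| dr | 1 μm | radial step |

The end-of-experiment radius is not printed anywhere; we fixed it from the
day geometry (day-5 treatment must fall inside the window of inefficacy,
which closes at ≈ 4700 μm, and colonies are imaged daily through day 9),
giving 750 μm of radial growth per day and a day-9 radius of 7500 μm. The
efficacy at the final radius is sensitive to this choice (≈ 0.31–0.36 at
6000 μm vs ≈ 0.55–0.63 at 7500 μm); `analysis/03_survival_efficacy.py`
prints the whole radius sweep so the dependence is visible, and
`analysis/02_width_equilibrium.py` sweeps r₀ (the equilibrium width is
insensitive: 49/47/46 μm at r₀ = 1000/1500/2000 μm).

### Numerics

- Midpoint radius (r + dr/2) in the arc→angle conversion: second-order
  accurate, so logarithmic closed forms hold to < 10⁻⁸ at dr = 1 μm.
- The width entering s_eff is the pre-step width (explicit Euler in the
  width dependence): first-order convergence to the width ODE, verified at
  dr = 0.1 and 0.01.
- Ties in simultaneous annihilation: most negative residual width first.
- One seeded `numpy` Generator per run; boundary order fixes the noise
  stream, so runs are bit-reproducible.
- Engine cost is O(boundaries) per step with vectorized noise; a full
  10⁴-clone, 6000-step run takes ~6 s on one CPU.

## 2. Reduced agent-based colony (`isbalance.abm`)

A desk-scale re-implementation of the standard off-lattice 2D colony/tumor
architecture: cells with area a grow at rate·ramp(c)·(adult area/2) per
hour (linear in time; division at the adult area into two half-area
daughters along a random direction), where ramp(c) is piecewise-linear
between c_halt = 0.2 and c_full = 0.6 of the boundary nutrient level; R-
cells carry rate factor (1 − s), s = 0.21. Nutrient obeys quasi-static
diffusion–uptake, D∇²c = u·ρ·c, solved by conjugate-gradient relaxation on
a 12 μm grid with a circular Dirichlet ring tracking the colony front at a
60 μm margin; D/u sets a penetration depth of ≈ 4 cell diameters, producing
a peripheral growth layer and a quiescent core. Mechanics are overdamped
pairwise repulsion v = k·(1 − d/d_c)² (zero at contact d_c = sum of radii,
no adhesion or motility), sub-stepped 8× per 0.1 h cycle step with a
displacement guard (halve dt and retry). The exact rates and force
constants are declared free parameters — only the qualitative architecture
(growth layer + repulsion + cost) drives the phenomenon — and were chosen
for a constant front speed (~3 μm/h) and a growth layer a few cells deep.

Initialization is a dense hollow ring (3 rows) ending at `ring_radius`, with
16.6% of the outermost-row positions replaced by single R- cells, evenly
spaced with a minimum angular gap; each is its own lineage. Compensation
is either stochastic (each front R- cell flips R-→R+ with probability μ per
cycle step; μ = 0.1 in the escape analyses) or triggered (exactly one front
R- cell per surviving clone flips when the colony radius first exceeds r*).
Bulk cells never flip, mirroring the observation that bulk compensation is
irrelevant to front dynamics.

The front is annotated by angular bins of ~one cell diameter: front cells
are those within one diameter of their bin's outermost cell; consecutive
bins sharing (lineage, type) form arcs (wrap-aware), reported in μm and
cell diameters and emitted in the same trajectory-table schema the
random-walk model uses, so every statistic runs unchanged. Life-history
phases (establishment → equilibrium → transition → escaped) are assigned
sticky in that order from the width trajectory and the first compensated
front cell, with the escape width fixed at 6 cells.

**Scale.** Colonies here reach ~3–10×10³ cells (vs ~2×10⁶ at full scale).
All agent-based claims are therefore checked as scale-robust bounds: the
uncompensated front width is small (≈ 1 cell diameter at this scale, vs
3.27 ± 1.86 at full scale) and stationary, front speed is constant, escaped
clones (> 6 cells) essentially never go extinct (< 1% — 0 observed among
~8 escapes in the reduced acceptance ensemble). The full-scale equilibrium
width cannot be reproduced without the original parameter table.

## 3. Statistics (`isbalance.stats`)

- **Tracking**: greedy nearest-circular-centroid matching of contiguous arc
  groups between consecutive snapshots within a 0.05 rad gate; unmatched
  current groups attach to an overlapping parent (subclone emergence) or
  start a new lineage; unmatched previous groups are extinct. On synthetic
  tables with 25 well-segregated clones, default segmentation noise and
  2 μm quantization, ≥ 99% of arcs are correctly assigned; accuracy
  degrades (to ~96–98%) as clone density grows and clones physically
  collide, an ambiguity no tracker can resolve.
- **Survival / failure**: a lineage is alive at r if it has any front
  segment; P_surv = n/n₀ with Poisson σ = √n/n₀. A lineage present at the
  treatment radius counts as one prospective resurgent growth dome
  (regrowth is not simulated); a dome is compensated if any front segment
  is R+ ("any detectable compensation" convention).
- **Efficacy**: E = 1 − P_no/P_with, first-order error propagation of the
  two Poisson σs; E is NaN where P_with = 0. The window of inefficacy is
  the largest grid radius with |E| ≤ one propagated SD ("zero within
  errors" is not defined more precisely in the source; one SD is our
  choice).
- **Widths**: per snapshot and type, a clone's width is the summed arc of
  its segments of that type; median/IQR/mean with linear (midpoint)
  quartile interpolation; `exclude_mixed` drops lineages carrying both
  types at a snapshot (the experimental convention for ambiguous
  segmentation; simulated subclones are typed exactly, so the default
  keeps them separate). The equilibrium width is the median of
  per-snapshot medians over a plateau range (default: upper half of the
  radius range).
- **Width distributions**: Gaussian KDE on ln w (Silverman bandwidth by
  default), back-transformed as f(w) = g(ln w)/w — supported on w > 0,
  exactly zero at the origin, normalized to 1 ± 10⁻³ on the returned grid;
  observations below the one-pixel cut-off are discarded first.

## 4. Estimators (`isbalance.estimators`)

- **Mutation rate**: orthogonal distance regression (scipy.odr) of
  f_blue(r) = 1 − f_red(r₀)·e^(μ(r₀−r)) with r₀ fixed to the first radius;
  f_red(r₀) defaults to the first observation, or can be fixed (e.g. to 1
  for a pure uncompensated inoculum, which removes a ~1% anchoring bias).
  Noiseless recovery is exact to 10⁻⁶; at σ_f = 0.02 the estimator is
  unbiased (200 replicates) and its reported σ has ~64–68% empirical
  coverage (500 replicates).
- **Fitness**: ODR fit of φ(r) = φ₀ + 2·√(s(2+s))·ln(r/r₀); the slope
  magnitude inverts to ŝ = √(1 + (m/2)²) − 1, a negative slope flags a
  shrinking (slower) focal sector. Exact noiseless recovery; within 20% on
  low-noise simulated sectors.
- **Escape**: per ensemble of runs compensated at the same r*, the mean
  compensated width vs radius is fitted linearly; Δr_escape =
  (w_escape − w_init)/slope with w_init = one cell diameter (the nucleus);
  P_escape = fraction of compensated clones exceeding 6 cells within the
  horizon; P_total = P_escape · P_mutate(w̄(r*)) holds exactly by
  construction. Runs with no clone alive at r* are excluded and counted.

## 5. Synthetic data (`isbalance.synth`)

The generator emulates what the imaging/segmentation pipeline would emit:
daily snapshots (nine radial increments of 750 μm), per-arc angular jitter
(default σ = 0.002 rad), width quantization to the pixel size (default
2 μm — a plausible microscope scale, a free test parameter, not a claim),
and withheld lineage identities with a parallel ground-truth table
(row-linked via `arc_id`). Scenario tables either delegate to the
random-walk engine (neutral / constant-cost / width-dependent, with packed
initial placement so clones start well-segregated, as inoculated single
cells do) or follow explicit scripted width functions and extinction radii.
With zero noise and zero pixel size the observed table is bit-identical to
the truth.

What a green closed-loop test establishes: the statistics and estimators
correctly invert the generator's forward model (including its noise). What
it does not establish: robustness to real segmentation pathologies —
misclassification, merged clones of the same color, uneven illumination —
which are outside the noise model by design.

## 6. Known limitations

- Clones in the random-walk model never interact; dense-front effects
  between neighboring resistant clones (merging, jostling) are absent.
- The compensated-nucleus insertion rule is a choice; alternatives (edge
  nucleation, multi-cell nuclei) would shift P_comp at fixed μ.
- The agent-based model omits cell death, adhesion, motility and 3D; its
  quantitative widths are scale-dependent and only bounds are asserted.
- The end-of-experiment radius (7500 μm) is inferred from day geometry, not
  printed; the efficacy endpoint inherits that uncertainty (see §1).
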