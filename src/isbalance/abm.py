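"""Reduced off-lattice agent-based model of a radially expanding colony.

A desk-scale 2D re-implementation of the PhysiCell-style in silico tumor:
cells grow and divide depending on a diffusible nutrient supplied from a
circular Dirichlet boundary and consumed by the cells, which confines
proliferation to a peripheral growth layer; cells interact through a
short-range polynomial repulsion and move overdamped (velocity = force /
drag, no motility, no adhesion).  Slower-growing resistant cells (R-) carry
a fitness cost s on their cycling rate; compensatory mutations (R- → R+)
restore the wild-type rate and can occur stochastically per cycle step or be
triggered for every surviving front clone when the colony first reaches a
radius r*.

The exact rates and force coefficients are declared model parameters (the
phenomenon — inflation-selection balance — is robust to them); defaults are
chosen to give a growth layer a few cell diameters thick and a constant
front speed.  The population starts as a dense hollow ring with single
resistant cells interspersed at the periphery (16.6% by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import cg
from scipy.spatial import cKDTree

from .rw import RM, RP, WT, _TYPE_STR
from .tables import SCHEMA, TrajectoryTable

__all__ = [
    "ABMConfig",
    "CellPopulation",
    "NutrientField",
    "SolverError",
    "initialize_ring",
    "relax_nutrient",
    "mechanics_step",
    "cycle_step",
    "apply_mutations",
    "annotate_front",
    "classify_phases",
    "run_abm",
]


class SolverError(RuntimeError):
    """Nutrient relaxation failed to reach the residual tolerance."""


@dataclass
class ABMConfig:
    """Parameters of the reduced agent-based colony.

    ``cell_diameter`` is the adult (division-ready) diameter; daughters are
    born at half the adult area.  The fitness cost ``s`` scales the R- cycle
    rate by (1 − s).  Nutrient units are dimensionless (1 at the Dirichlet
    ring, which tracks the colony front at ``dirichlet_margin``); only the
    ratio of diffusion to uptake matters and sets the growth-layer depth
    sqrt(n_diffusion / (uptake · cell density)) ≈ 4 cell diameters at the
    defaults.
    """

    cell_diameter: float = 12.0
    wt_division_rate: float = 0.45        # divisions/h at saturating nutrient
    s: float = 0.21
    mutation_mode: str = "none"           # none | stochastic | triggered
    mu_per_step: float = 0.0
    r_star: float | None = None
    mutant_fraction: float = 0.166
    ring_radius: float = 90.0
    ring_rows: int = 3
    min_mut_gap_cells: int = 2
    # nutrient
    n_diffusion: float = 1000.0
    uptake: float = 40.0
    dirichlet_value: float = 1.0
    dirichlet_margin: float = 60.0
    c_halt: float = 0.2
    c_full: float = 0.6
    grid_dx: float = 12.0
    nutrient_tol: float = 1e-8
    nutrient_maxiter: int = 4000
    # mechanics
    repulsion: float = 60.0               # μm/h at full overlap
    mech_substeps: int = 8
    # stepping / termination
    dt_cycle: float = 0.1                 # h
    r_final: float = 420.0
    max_cells: int = 200_000
    t_max: float = 2000.0
    snapshot_every_h: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.s < 1):
            raise ValueError("fitness cost s must lie in [0, 1)")
        if not (0 <= self.mutant_fraction <= 1):
            raise ValueError("mutant_fraction must lie in [0, 1]")
        if self.c_halt >= self.c_full:
            raise ValueError("need c_halt < c_full")
        if min(self.wt_division_rate, self.dt_cycle, self.grid_dx,
               self.cell_diameter, self.n_diffusion) <= 0:
            raise ValueError("rates, steps and scales must be positive")

    @property
    def adult_area(self) -> float:
        return math.pi * (self.cell_diameter / 2.0) ** 2


class CellPopulation:
    """Off-lattice cells as flat arrays (positions, areas, types, lineages)."""

    def __init__(self, x, y, area, ctype, lineage):
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.area = np.asarray(area, dtype=float)
        self.ctype = np.asarray(ctype, dtype=np.int8)
        self.lineage = np.asarray(lineage, dtype=np.int32)
        self.quiescent = np.zeros(self.x.size, dtype=bool)

    @property
    def n(self) -> int:
        return self.x.size

    @property
    def radius(self) -> np.ndarray:
        """Per-cell physical radius from area."""
        return np.sqrt(self.area / math.pi)

    @property
    def r(self) -> np.ndarray:
        """Per-cell distance from the colony center."""
        return np.hypot(self.x, self.y)

    def colony_radius(self) -> float:
        return float(self.r.max()) if self.n else 0.0

    def validate(self) -> None:
        if np.any(~np.isfinite(self.x)) or np.any(~np.isfinite(self.y)):
            raise AssertionError("non-finite cell positions")
        if np.any(self.area <= 0):
            raise AssertionError("non-positive cell areas")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "x": self.x, "y": self.y, "r_cell": self.radius,
            "type": [_TYPE_STR[t] for t in self.ctype],
            "lineage": self.lineage, "quiescent": self.quiescent,
        })


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def initialize_ring(config: ABMConfig, rng: np.random.Generator | None = None) -> CellPopulation:
    """Dense hollow ring with single resistant cells at the periphery.

    ``ring_rows`` concentric rows of cells end at ``ring_radius``; a fraction
    ``mutant_fraction`` of the outermost-row positions hold single R- cells
    (lineages 1..k), spaced at least ``min_mut_gap_cells`` positions apart.
    """
    rng = rng or np.random.default_rng(config.seed)
    d = config.cell_diameter
    xs, ys, types, lin = [], [], [], []
    n_outer = None
    for k in range(config.ring_rows):
        rad = config.ring_radius - 0.9 * d * k
        if rad <= d:
            break
        m = max(8, int(2 * math.pi * rad / d))
        ang = (np.arange(m) + 0.5 * (k % 2)) * 2 * math.pi / m
        xs.append(rad * np.cos(ang))
        ys.append(rad * np.sin(ang))
        types.append(np.full(m, WT, dtype=np.int8))
        lin.append(np.zeros(m, dtype=np.int32))
        if k == 0:
            n_outer = m
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    ctype = np.concatenate(types)
    lineage = np.concatenate(lin)

    n_mut = int(round(config.mutant_fraction * n_outer))
    if n_mut > 0:
        if n_mut * config.min_mut_gap_cells > n_outer:
            raise ValueError(
                f"cannot place {n_mut} mutants with gap {config.min_mut_gap_cells} "
                f"among {n_outer} peripheral positions"
            )
        slots = np.round(np.linspace(0, n_outer, n_mut, endpoint=False)).astype(int)
        ctype[slots] = RM
        lineage[slots] = np.arange(1, n_mut + 1)

    area = config.adult_area * rng.uniform(0.5, 0.95, x.size)
    pop = CellPopulation(x, y, area, ctype, lineage)
    pop.validate()
    return pop


# ---------------------------------------------------------------------------
# nutrient
# ---------------------------------------------------------------------------

class NutrientField:
    """Dimensionless nutrient on a square grid with a circular Dirichlet ring."""

    def __init__(self, extent: float, dx: float, c_boundary: float = 1.0):
        self.dx = float(dx)
        n = 2 * int(math.ceil(extent / dx)) + 1
        self.nx = n
        self.xs = (np.arange(n) - n // 2) * dx
        self.c = np.full((n, n), c_boundary)
        self.c_boundary = float(c_boundary)
        self.dirichlet_radius = float(extent)
        gx, gy = np.meshgrid(self.xs, self.xs, indexing="ij")
        self._rr = np.hypot(gx, gy)

    def indices_of(self, x, y):
        i = np.clip(np.round(x / self.dx).astype(int) + self.nx // 2, 0, self.nx - 1)
        j = np.clip(np.round(y / self.dx).astype(int) + self.nx // 2, 0, self.nx - 1)
        return i, j

    def value_at(self, x, y):
        i, j = self.indices_of(np.asarray(x), np.asarray(y))
        return self.c[i, j]

    def radial_profile(self, nbins: int = 40):
        """Radially averaged concentration (bin centers, means)."""
        rmax = self.dirichlet_radius
        bins = np.linspace(0, rmax, nbins + 1)
        idx = np.digitize(self._rr.ravel(), bins) - 1
        prof = np.array([
            self.c.ravel()[idx == k].mean() if np.any(idx == k) else np.nan
            for k in range(nbins)
        ])
        return 0.5 * (bins[:-1] + bins[1:]), prof


def relax_nutrient(field: NutrientField, pop: CellPopulation, config: ABMConfig,
                   dirichlet_radius: float | None = None) -> NutrientField:
    """Quasi-steady nutrient: diffusion balances per-cell uptake (in place).

    Solves D ∇²c = uptake·ρ(x)·c with c fixed at ``dirichlet_value`` on and
    outside the circular boundary, by conjugate-gradient relaxation warm-
    started from the previous solution; raises :class:`SolverError` with the
    residual when the tolerance is not reached.
    """
    if dirichlet_radius is None:
        dirichlet_radius = min(
            pop.colony_radius() + config.dirichlet_margin,
            field.dirichlet_radius,
        )
    n, dx = field.nx, field.dx
    counts = np.zeros((n, n))
    i, j = field.indices_of(pop.x, pop.y)
    np.add.at(counts, (i, j), 1.0)

    interior = field._rr < dirichlet_radius
    idx = -np.ones((n, n), dtype=int)
    ii, jj = np.nonzero(interior)
    m = ii.size
    idx[ii, jj] = np.arange(m)
    k_upt = config.uptake * counts[ii, jj] / config.n_diffusion  # dimensionless sink

    rows, cols, vals = [], [], []
    b = np.zeros(m)
    diag = 4.0 + k_upt
    rows.append(np.arange(m)); cols.append(np.arange(m)); vals.append(diag)
    for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        ni, nj = ii + di, jj + dj
        inb = (ni >= 0) & (ni < n) & (nj >= 0) & (nj < n)
        nbr_idx = np.where(inb, idx[np.clip(ni, 0, n - 1), np.clip(nj, 0, n - 1)], -1)
        is_unknown = nbr_idx >= 0
        rows.append(np.arange(m)[is_unknown])
        cols.append(nbr_idx[is_unknown])
        vals.append(np.full(is_unknown.sum(), -1.0))
        np.add.at(b, np.arange(m)[~is_unknown], config.dirichlet_value)
    A = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(m, m),
    )
    x0 = field.c[ii, jj]
    sol, _info = cg(A, b, x0=x0, rtol=0.0, atol=config.nutrient_tol,
                    maxiter=config.nutrient_maxiter)
    resid = float(np.abs(A @ sol - b).max())
    if resid > max(config.nutrient_tol * 100, 1e-6):
        raise SolverError(f"nutrient relaxation stalled at residual {resid:.3e}")
    field.c = np.full((n, n), config.dirichlet_value)
    field.c[ii, jj] = np.clip(sol, 0.0, config.dirichlet_value)
    return field


# ---------------------------------------------------------------------------
# mechanics & cycling
# ---------------------------------------------------------------------------

def _pair_list(pop: CellPopulation, config: ABMConfig, skin: float = 2.0):
    tree = cKDTree(np.c_[pop.x, pop.y])
    pairs = tree.query_pairs(config.cell_diameter + skin, output_type="ndarray")
    return pairs


def mechanics_step(pop: CellPopulation, dt: float, config: ABMConfig,
                   pairs: np.ndarray | None = None, max_retries: int = 6) -> CellPopulation:
    """One overdamped relaxation step of the polynomial contact repulsion.

    Pairs closer than the sum of their radii feel v = repulsion·(1−d/d_c)²
    directed apart (zero exactly at contact, no attraction); positions move
    by v·dt.  A step that would displace any cell by more than one cell
    radius is retried with a halved dt (bounded retries).
    """
    if pairs is None:
        pairs = _pair_list(pop, config)
    if pairs.size == 0:
        return pop
    remaining = dt
    for _ in range(max_retries + 1):
        dxp = pop.x[pairs[:, 0]] - pop.x[pairs[:, 1]]
        dyp = pop.y[pairs[:, 0]] - pop.y[pairs[:, 1]]
        d = np.hypot(dxp, dyp)
        rads = pop.radius
        d_c = rads[pairs[:, 0]] + rads[pairs[:, 1]]
        overlap = d < d_c
        if not np.any(overlap):
            return pop
        p = pairs[overlap]
        d = np.maximum(d[overlap], 1e-6)
        mag = config.repulsion * (1.0 - d / d_c[overlap]) ** 2
        ux, uy = dxp[overlap] / d, dyp[overlap] / d
        vx = np.zeros(pop.n)
        vy = np.zeros(pop.n)
        np.add.at(vx, p[:, 0], mag * ux)
        np.add.at(vy, p[:, 0], mag * uy)
        np.add.at(vx, p[:, 1], -mag * ux)
        np.add.at(vy, p[:, 1], -mag * uy)
        speed = np.hypot(vx, vy)
        if speed.max() * remaining > rads.min():
            remaining *= 0.5
            continue
        pop.x = pop.x + vx * remaining
        pop.y = pop.y + vy * remaining
        return pop
    raise RuntimeError("mechanics step failed to satisfy displacement bound")


def _growth_ramp(c, config: ABMConfig):
    return np.clip((c - config.c_halt) / (config.c_full - config.c_halt), 0.0, 1.0)


def cycle_step(pop: CellPopulation, field: NutrientField, dt: float,
               config: ABMConfig, rng: np.random.Generator) -> CellPopulation:
    """Nutrient-dependent growth and division (in place).

    Cell area grows linearly at rate·ramp(c)·(adult area / 2) per hour, with
    the R- rate scaled by (1 − s); a cell reaching adult area splits into two
    half-area daughters offset along a random direction, inheriting type and
    lineage.  Cells with ramp = 0 are flagged quiescent.
    """
    c = field.value_at(pop.x, pop.y)
    ramp = _growth_ramp(c, config)
    pop.quiescent = ramp <= 0.0
    rate = np.where(pop.ctype == RM,
                    config.wt_division_rate * (1.0 - config.s),
                    config.wt_division_rate)
    pop.area = pop.area + rate * ramp * (config.adult_area / 2.0) * dt

    dividing = np.nonzero(pop.area >= config.adult_area)[0]
    if dividing.size:
        half = pop.area[dividing] / 2.0
        r_d = np.sqrt(half / math.pi)
        ang = rng.uniform(0, 2 * math.pi, dividing.size)
        ox, oy = 0.5 * r_d * np.cos(ang), 0.5 * r_d * np.sin(ang)
        pop.area[dividing] = half
        newx = pop.x[dividing] + ox
        newy = pop.y[dividing] + oy
        pop.x[dividing] -= ox
        pop.y[dividing] -= oy
        pop.x = np.concatenate([pop.x, newx])
        pop.y = np.concatenate([pop.y, newy])
        pop.area = np.concatenate([pop.area, half])
        pop.ctype = np.concatenate([pop.ctype, pop.ctype[dividing]])
        pop.lineage = np.concatenate([pop.lineage, pop.lineage[dividing]])
        pop.quiescent = np.concatenate([pop.quiescent, pop.quiescent[dividing]])
    return pop


# ---------------------------------------------------------------------------
# mutations
# ---------------------------------------------------------------------------

def apply_mutations(pop: CellPopulation, config: ABMConfig,
                    rng: np.random.Generator, front_mask: np.ndarray,
                    triggered_done: bool = False):
    """Compensatory R- → R+ flips at the front (in place).

    Stochastic mode flips each front R- cell with probability ``mu_per_step``
    per cycle step; triggered mode flips exactly one front R- cell (the
    outermost) per surviving front clone the first time the colony radius
    exceeds ``r_star``.  Returns ``(pop, n_flips, triggered_done)``.
    """
    n_flips = 0
    if config.mutation_mode == "stochastic" and config.mu_per_step > 0:
        cand = np.nonzero(front_mask & (pop.ctype == RM))[0]
        if cand.size:
            hit = cand[rng.random(cand.size) < config.mu_per_step]
            pop.ctype[hit] = RP
            n_flips = hit.size
    elif config.mutation_mode == "triggered" and not triggered_done:
        if config.r_star is None:
            raise ValueError("triggered mode needs r_star")
        if pop.colony_radius() >= config.r_star:
            cand = np.nonzero(front_mask & (pop.ctype == RM))[0]
            r = pop.r
            for lid in np.unique(pop.lineage[cand]):
                mine = cand[pop.lineage[cand] == lid]
                pop.ctype[mine[np.argmax(r[mine])]] = RP
                n_flips += 1
            triggered_done = True  # a no-op (n_flips = 0) is still recorded
    return pop, n_flips, triggered_done


# ---------------------------------------------------------------------------
# front annotation
# ---------------------------------------------------------------------------

def _front_bins(pop: CellPopulation, cell_diameter: float):
    """Angular binning of the periphery: per-bin outermost cell and mask."""
    r = pop.r
    theta = np.arctan2(pop.y, pop.x) % (2 * math.pi)
    r_col = r.max()
    n_bins = max(16, int(2 * math.pi * r_col / cell_diameter))
    bins = np.minimum((theta / (2 * math.pi) * n_bins).astype(int), n_bins - 1)
    r_bin = np.full(n_bins, -np.inf)
    np.maximum.at(r_bin, bins, r)
    front_mask = r >= r_bin[bins] - cell_diameter
    # outermost cell per bin
    order = np.lexsort((r, bins))
    rep = np.full(n_bins, -1, dtype=int)
    rep[bins[order]] = order  # last write per bin has max r
    return n_bins, bins, r_bin, front_mask, rep


def annotate_front(pop: CellPopulation, cell_diameter: float = 12.0) -> pd.DataFrame:
    """Identify the outermost cell shell and group it into front clones.

    The periphery is divided into angular bins of roughly one cell diameter;
    the front is every cell within one cell diameter of its bin's outermost
    cell.  Consecutive bins whose outermost cell shares lineage and type form
    an arc (wrap-aware); arcs are reported with angular extent, arc width in
    μm and in cell diameters.
    """
    if pop.n == 0:
        raise ValueError("empty population has no front")
    n_bins, bins, r_bin, front_mask, rep = _front_bins(pop, cell_diameter)
    occupied = rep >= 0
    if not np.all(occupied):
        # colony with angular gaps (early ring): drop empty bins
        valid = np.nonzero(occupied)[0]
    else:
        valid = np.arange(n_bins)
    lid = pop.lineage[rep[valid]]
    typ = pop.ctype[rep[valid]]
    rad = r_bin[valid]
    binw = 2 * math.pi / n_bins

    # runs of identical (lineage, type) over the valid bins, wrap-aware
    k = valid.size
    breaks = np.nonzero((lid != np.roll(lid, 1)) | (typ != np.roll(typ, 1)))[0]
    rows = []
    if breaks.size == 0:
        rows.append((int(lid[0]), int(typ[0]), 0.0, 2 * math.pi, float(rad.mean())))
    else:
        for bstart, bend in zip(breaks, np.r_[breaks[1:], breaks[0] + k]):
            sel = np.arange(bstart, bend) % k
            th0 = valid[bstart] * binw
            th1 = th0 + sel.size * binw
            rows.append((int(lid[sel[0]]), int(typ[sel[0]]), th0, th1,
                         float(rad[sel].mean())))
    out = pd.DataFrame(rows, columns=["lineage_id", "type_code", "theta_start_rad",
                                      "theta_end_rad", "r_front"])
    out["subclone_type"] = [_TYPE_STR[t] for t in out["type_code"]]
    out["arc_width_um"] = (out["theta_end_rad"] - out["theta_start_rad"]) * out["r_front"]
    out["arc_cells"] = out["arc_width_um"] / cell_diameter
    return out


def classify_phases(widths_cells, has_rp, w_escape_cells: float = 6.0,
                    eq_band: float = 0.5, establish_cells: float = 2.0):
    """Label a clone's life-history phases from its front-width trajectory.

    Phases are sticky in the order establishment → equilibrium → transition
    → escaped: equilibrium once the width settles within ±``eq_band`` of its
    running median (and above ``establish_cells``) before any compensation,
    transition from the first compensated front cell, escaped once the width
    exceeds ``w_escape_cells``.
    """
    widths = np.asarray(widths_cells, dtype=float)
    has_rp = np.asarray(has_rp, dtype=bool)
    labels = []
    phase = "establishment"
    for i, (w, rp) in enumerate(zip(widths, has_rp)):
        if phase in ("establishment", "equilibrium") and rp:
            phase = "transition"
        if phase == "transition" and w > w_escape_cells:
            phase = "escaped"
        if phase == "establishment" and w >= establish_cells:
            med = np.median(widths[: i + 1])
            if abs(w - med) <= eq_band * max(med, 1e-9):
                phase = "equilibrium"
        labels.append(phase)
    return labels


# ---------------------------------------------------------------------------
# full simulation
# ---------------------------------------------------------------------------

def run_abm(config: ABMConfig):
    """Grow the colony and emit the shared trajectory-table schema.

    Loop per cycle step: quasi-static nutrient relaxation → growth/division →
    mutations → sub-stepped mechanics.  Snapshots (every
    ``snapshot_every_h``) record the front annotation of every resistant
    lineage; the returned table uses the colony radius as the snapshot
    radius, so the clone statistics run unchanged.

    Returns ``(table, annotations)`` where annotations is a list of
    ``(t_hours, colony_radius, front DataFrame)``.
    """
    rng = np.random.default_rng(config.seed)
    pop = initialize_ring(config, rng)
    extent = config.r_final + config.dirichlet_margin + 3 * config.grid_dx
    field = NutrientField(extent, config.grid_dx, config.dirichlet_value)

    t = 0.0
    next_snap = 0.0
    triggered_done = False
    rows: list[tuple] = []
    annotations: list[tuple] = []
    n_mut0 = int(pop.lineage.max())

    while True:
        relax_nutrient(field, pop, config)
        cycle_step(pop, field, config.dt_cycle, config, rng)
        if config.mutation_mode != "none":
            _, _, _, front_mask, _ = _front_bins(pop, config.cell_diameter)
            pop, _, triggered_done = apply_mutations(
                pop, config, rng, front_mask, triggered_done)
        pairs = _pair_list(pop, config)
        dt_m = config.dt_cycle / config.mech_substeps
        for _ in range(config.mech_substeps):
            mechanics_step(pop, dt_m, config, pairs=pairs)
        t += config.dt_cycle

        if t >= next_snap - 1e-9:
            front = annotate_front(pop, config.cell_diameter)
            r_col = pop.colony_radius()
            annotations.append((t, r_col, front))
            res = front[front["lineage_id"] > 0]
            for _, a in res.iterrows():
                rows.append((r_col, int(a["lineage_id"]), a["subclone_type"],
                             a["theta_start_rad"], a["theta_end_rad"],
                             a["arc_width_um"]))
            next_snap += config.snapshot_every_h

        if (pop.colony_radius() >= config.r_final or pop.n >= config.max_cells
                or t >= config.t_max):
            break

    df = pd.DataFrame(rows, columns=SCHEMA)
    meta = {
        "generator": "abm_simulator",
        "config": {k: v for k, v in asdict(config).items()},
        "n0": n_mut0,
        "t_final_h": t,
        "n_cells": pop.n,
    }
    meta["config"]["r_final"] = float(pop.colony_radius())
    return TrajectoryTable(df, meta), annotations
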