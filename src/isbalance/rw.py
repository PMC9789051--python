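"""Sector boundaries as selection-biased random walks on an inflating front.

Each resistant clone on the periphery of a radially expanding colony is a set
of contiguous typed segments (uncompensated resistant ``R-``, compensated
``R+``) delimited by boundaries that perform independent 1D random walks in
angular space.  Per radial step ``dr`` a boundary at angle Φ moves

    Φ  <-  Φ + η(b_eff, σ_X) / r,        σ_X² = 4 · D · dr,

where ``η(m, σ)`` is Gaussian noise with mean ``m`` and standard deviation
``σ`` (both in arc-length units, μm), and the bias ``b_eff`` points into the
less-fit of the two adjacent segments.  Each walker carries the equal-time
bias

    b(s) = sqrt(|s| (2 + s))

per μm of radial growth, so the width of a sector flanked by two fitter
neighbors shrinks deterministically at 2·b(s) (both boundaries drift
inward), and the full opening angle of a *faster* sector widens as
φ(r) = φ0 + 2 b ln(r/r0) — the form used by the opening-angle fitness
assay.  Inflation needs no explicit term: angular extents are carried
outward, w = r·Δθ.

Selection is either the full cost (``null``), a constant-rescaled cost
(``constant_scaled``), or width-dependent (``width_dependent``), the latter
through the logistic effective coefficient

    s_eff(w) = s0 · 2 / (1 + exp(w_c / w)),

which vanishes faster than linearly as w → 0 and therefore admits a *stable*
inflation-selection balance.  Boundaries annihilate when they cross (clonal
extinction of the enclosed segment), and R- segments nucleate compensated
subsegments at rate μ per cell per μm of radial growth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .tables import R_MINUS, R_PLUS, SCHEMA, TrajectoryTable

# integer type codes used in the engine
WT, RM, RP = 0, 1, 2
_TYPE_STR = {WT: "WT", RM: R_MINUS, RP: R_PLUS}
_STR_TYPE = {v: k for k, v in _TYPE_STR.items()}


# ---------------------------------------------------------------------------
# elementary relations
# ---------------------------------------------------------------------------

def bias_from_selection(s, absolute: bool = False):
    """Lateral boundary drift b = sqrt(|s|(2+s)) per μm of radial growth.

    ``s`` is the relative fitness difference across the boundary.  Fitness
    costs may be passed as negative values only with ``absolute=True``.
    """
    s = np.asarray(s, dtype=float)
    if np.any(s < 0) and not absolute:
        raise ValueError("negative s requires absolute=True")
    out = np.sqrt(np.abs(s) * (2.0 + s))
    return float(out) if out.ndim == 0 else out


def effective_selection(w, s0: float, w_c: float):
    """Width-dependent effective selection s_eff(w) = s0·2/(1+e^{w_c/w}).

    Vanishes (superexponentially) at w → 0+ and saturates to ``s0`` as
    w → ∞; strictly increasing in w.
    """
    if w_c <= 0:
        raise ValueError("w_c must be positive")
    w = np.asarray(w, dtype=float)
    if np.any(w < 0):
        raise ValueError("width must be non-negative")
    with np.errstate(divide="ignore", over="ignore"):
        expo = np.where(w > 0, w_c / np.maximum(w, 1e-300), np.inf)
        out = np.where(expo < 700.0, s0 * 2.0 / (1.0 + np.exp(np.minimum(expo, 700.0))), 0.0)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class RWConfig:
    """Parameters of the boundary-random-walk model.

    Defaults are the calibrated colony values: fitness cost s0 = 0.013,
    critical width w_c = 280 μm, genetic-drift coefficient D = 0.23 (per-step
    arc variance 4·D·dr, dr in μm), compensatory mutation rate
    μ = 1e-4 per cell per μm of radial growth, initial clone widths
    ~ N(20, 5) μm truncated positive.  The radius range emulates the imaging
    experiment: day-1 reference radius r0 = 1500 μm and nine daily snapshots
    of 750 μm radial growth each, ending at 7500 μm.
    """

    s0: float = 0.013
    w_c: float = 280.0
    D: float = 0.23
    mu: float = 1e-4
    r0: float = 1500.0
    r_final: float = 7500.0
    dr: float = 1.0
    n0: int = 1000
    init_width_mean: float = 20.0
    init_width_sd: float = 5.0
    selection_mode: str = "width_dependent"  # null | constant_scaled | width_dependent
    constant_factor: float = 1.0
    cell_diameter: float = 12.0
    mutation_kinetics: str = "per_cell"  # per_cell | per_clone_constant_rate
    require_packing: bool = False
    snapshot_dr: float | None = None  # default: (r_final-r0)/8, 9 daily images
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s0 < 0:
            raise ValueError("s0 must be >= 0 (a cost; sign handled internally)")
        if self.w_c <= 0 or self.D < 0 or self.mu < 0:
            raise ValueError("invalid w_c, D or mu")
        if not (0 < self.dr <= self.r_final - self.r0):
            raise ValueError("need 0 < dr <= r_final - r0")
        if self.n0 < 1:
            raise ValueError("n0 >= 1 required")
        if self.selection_mode not in ("null", "constant_scaled", "width_dependent"):
            raise ValueError(f"unknown selection_mode {self.selection_mode!r}")

    def selection_coefficient(self, w):
        """Effective cost applied at an R-/fitter boundary for R- width ``w``."""
        if self.selection_mode == "null":
            return np.broadcast_to(np.float64(self.s0), np.shape(w)).copy() if np.ndim(w) else self.s0
        if self.selection_mode == "constant_scaled":
            s = self.s0 * self.constant_factor
            return np.broadcast_to(np.float64(s), np.shape(w)).copy() if np.ndim(w) else s
        return effective_selection(w, self.s0, self.w_c)


# ---------------------------------------------------------------------------
# front state
# ---------------------------------------------------------------------------

class FrontState:
    """The colony periphery at radius ``r``.

    Boundaries are stored flat across lineages: ``theta`` ascending within
    each lineage block, with per-boundary left/right segment type codes
    (``WT`` outside the lineage extremes).  Segments are implicit between
    consecutive boundaries of the same lineage.  Wild-type fills all gaps, so
    typed extents plus wild-type gaps always cover the full 2π.
    """

    def __init__(self, r, theta, lin, ltype, rtype, events=None):
        self.r = float(r)
        self.theta = np.asarray(theta, dtype=float)
        self.lin = np.asarray(lin, dtype=np.int64)
        self.ltype = np.asarray(ltype, dtype=np.int8)
        self.rtype = np.asarray(rtype, dtype=np.int8)
        # (lineage_id, subclone type code, radius) extinction events
        self.events: list[tuple[int, int, float]] = events if events is not None else []

    # -- construction -----------------------------------------------------
    @classmethod
    def from_segments(cls, r, segments):
        """Build a front from ``(theta0, theta1, type, lineage_id)`` tuples.

        Segments of one lineage must be contiguous (share boundaries);
        wild-type gaps are implicit.
        """
        theta, lin, lt, rt = [], [], [], []
        by_lin: dict[int, list] = {}
        for th0, th1, typ, lid in segments:
            t = _STR_TYPE[typ] if isinstance(typ, str) else int(typ)
            by_lin.setdefault(int(lid), []).append((float(th0), float(th1), t))
        for lid in sorted(by_lin):
            segs = sorted(by_lin[lid])
            prev_type = WT
            for i, (th0, th1, t) in enumerate(segs):
                if th1 < th0:
                    raise ValueError("segment with negative extent")
                if i > 0 and abs(th0 - segs[i - 1][1]) > 1e-12:
                    raise ValueError("segments of one lineage must be contiguous")
                if i > 0 and t == segs[i - 1][2]:
                    raise ValueError("adjacent same-type segments must be merged")
                theta.append(th0)
                lin.append(lid)
                lt.append(prev_type)
                rt.append(t)
                prev_type = t
            theta.append(segs[-1][1])
            lin.append(lid)
            lt.append(prev_type)
            rt.append(WT)
        return cls(r, theta, lin, lt, rt)

    # -- views ------------------------------------------------------------
    @property
    def n_boundaries(self) -> int:
        return self.theta.size

    def lineage_ids(self) -> np.ndarray:
        return np.unique(self.lin)

    def segments(self):
        """Yield ``(lineage_id, type_code, theta0, theta1)`` typed segments."""
        th, li, rt = self.theta, self.lin, self.rtype
        for i in range(th.size - 1):
            if li[i] == li[i + 1] and rt[i] != WT:
                yield int(li[i]), int(rt[i]), float(th[i]), float(th[i + 1])

    def widths_by_lineage(self):
        """Total arc width per (lineage, type code) at the current radius."""
        out: dict[tuple[int, int], float] = {}
        for lid, t, th0, th1 in self.segments():
            out[(lid, t)] = out.get((lid, t), 0.0) + (th1 - th0) * self.r
        return out

    def validate(self) -> None:
        th, li, lt, rt = self.theta, self.lin, self.ltype, self.rtype
        if not np.all(np.diff(li) >= 0):
            raise AssertionError("lineage blocks not contiguous/sorted")
        same = li[:-1] == li[1:]
        if np.any(th[1:][same] < th[:-1][same] - 1e-12):
            raise AssertionError("angles not ascending within a lineage")
        if not np.all(rt[:-1][same] == lt[1:][same]):
            raise AssertionError("boundary type annotations inconsistent")
        # first/last boundary of each block faces wild type
        first = np.r_[True, ~same]
        last = np.r_[~same, True]
        if np.any(lt[first] != WT) or np.any(rt[last] != WT):
            raise AssertionError("lineage extremes must face wild type")
        # adjacent typed segments never share a type
        for i in range(th.size - 1):
            if same[i] and rt[i] != WT and lt[i] == rt[i]:
                raise AssertionError("boundary separating identical types")

    def copy(self) -> "FrontState":
        return FrontState(
            self.r, self.theta.copy(), self.lin.copy(), self.ltype.copy(),
            self.rtype.copy(), list(self.events),
        )


# ---------------------------------------------------------------------------
# single-step operations
# ---------------------------------------------------------------------------

def _boundary_bias(state: FrontState, config: RWConfig) -> np.ndarray:
    """Signed arc bias b(s) per boundary (μm per radial μm).

    A boundary drifts into the adjacent less-fit (R-) segment; its effective
    selection in width-dependent mode uses that segment's current width.
    WT|R+ boundaries are neutral.
    """
    th, li, lt, rt = state.theta, state.lin, state.ltype, state.rtype
    m = th.size
    if m == 0:
        return np.zeros(0)
    same = np.r_[li[:-1] == li[1:], False]
    wseg = np.zeros(m)  # width of segment right of boundary i (arc μm)
    wseg[:-1] = np.where(same[:-1], (th[1:] - th[:-1]) * state.r, 0.0)

    bias = np.zeros(m)
    right_rm = rt == RM
    left_rm = lt == RM
    if np.any(right_rm):
        w_adj = wseg[right_rm]
        s = config.selection_coefficient(np.maximum(w_adj, 0.0))
        bias[right_rm] = bias_from_selection(s)
    if np.any(left_rm):
        idx = np.nonzero(left_rm)[0]
        w_adj = wseg[idx - 1]
        s = config.selection_coefficient(np.maximum(w_adj, 0.0))
        bias[idx] = -bias_from_selection(s)
    return bias


def step_front(state: FrontState, config: RWConfig, rng: np.random.Generator) -> FrontState:
    """Advance all boundaries by one radial step ``dr`` (in place).

    Arc displacement per boundary ~ N(b_eff·dr, 4·D·dr), converted to angle
    with the midpoint radius r + dr/2 (the second-order-accurate choice; the
    bias still uses the pre-step widths).  Crossings are resolved separately by
    :func:`annihilate_and_merge`.
    """
    r = state.r
    bias = _boundary_bias(state, config)
    disp = bias * config.dr
    if config.D > 0:
        disp = disp + rng.normal(0.0, math.sqrt(4.0 * config.D * config.dr), size=state.theta.size)
    # midpoint radius: second-order accurate arc→angle conversion, so the
    # D = 0 limit reproduces the logarithmic closed forms to < 1e-8
    state.theta = state.theta + disp / (r + 0.5 * config.dr)
    state.r = r + config.dr
    return state


def annihilate_and_merge(state: FrontState) -> FrontState:
    """Remove collapsed segments and merge flanks (in place).

    A segment whose delimiting boundaries crossed is extinct at the current
    radius.  Flanking same-type segments merge (both boundaries removed);
    different-type flanks are separated by a single boundary placed at the
    midpoint of the crossed pair.  Simultaneous crossings within a lineage
    are resolved most-negative-residual-width first, rechecking after each
    removal.
    """
    th, li = state.theta, state.lin
    same = li[:-1] == li[1:]
    crossed = same & (th[1:] < th[:-1])
    if not np.any(crossed):
        return state
    bad_lineages = np.unique(li[:-1][crossed])
    changes = {}
    for lid in bad_lineages:
        a, b = np.searchsorted(li, [lid, lid + 1])
        new = _resolve_lineage(
            list(th[a:b]), list(state.ltype[a:b]), list(state.rtype[a:b]),
            int(lid), state.r, state.events,
        )
        changes[int(lid)] = new
    _splice(state, changes)
    return state


def _resolve_lineage(th, lt, rt, lid, r, events):
    """Resolve crossings in one lineage's boundary lists; return new lists."""
    while True:
        if len(th) < 2:
            break
        widths = [th[j + 1] - th[j] for j in range(len(th) - 1)]
        neg = [j for j, w in enumerate(widths) if w < 0]
        if not neg:
            break
        j = min(neg, key=lambda k: widths[k])  # deepest crossing first
        left, right = lt[j], rt[j + 1]
        events.append((lid, int(rt[j]), r))
        mid = 0.5 * (th[j] + th[j + 1])
        del th[j:j + 2], lt[j:j + 2], rt[j:j + 2]
        if left != right:
            th.insert(j, mid)
            lt.insert(j, left)
            rt.insert(j, right)
    return th, lt, rt


def nucleate_compensation(state: FrontState, config: RWConfig, rng: np.random.Generator) -> FrontState:
    """Insert compensated (R+) nuclei into R- segments (in place).

    Per radial step each R- segment of width w mutates with probability
    1 − exp(−μ·(w/cell_diameter)·dr) (or 1 − exp(−μ·dr) in
    ``per_clone_constant_rate`` mode).  A nucleus one cell diameter wide is
    placed uniformly inside the parent; parents narrower than one cell
    convert entirely.
    """
    if config.mu <= 0:
        return state
    th, li, rt = state.theta, state.lin, state.rtype
    same = np.r_[li[:-1] == li[1:], False]
    seg_i = np.nonzero(same & (rt == RM))[0]
    if seg_i.size == 0:
        return state
    w = (th[seg_i + 1] - th[seg_i]) * state.r
    w = np.maximum(w, 0.0)
    if config.mutation_kinetics == "per_clone_constant_rate":
        p = 1.0 - np.exp(-config.mu * config.dr * np.ones_like(w))
    else:
        p = 1.0 - np.exp(-config.mu * (w / config.cell_diameter) * config.dr)
    hits = seg_i[rng.random(seg_i.size) < p]
    if hits.size == 0:
        return state

    changes = {}
    for lid in np.unique(li[hits]):
        a, b = np.searchsorted(li, [lid, lid + 1])
        lth = list(th[a:b])
        llt = list(state.ltype[a:b])
        lrt = list(state.rtype[a:b])
        for i in sorted(hits[li[hits] == lid], reverse=True):
            j = i - a  # local index of segment's left boundary
            wseg = (lth[j + 1] - lth[j]) * state.r
            cd = config.cell_diameter
            if wseg <= cd:
                # whole-segment conversion; merge with R+ neighbors
                lrt[j] = RP
                llt[j + 1] = RP
                if j + 2 < len(lth) and lrt[j + 1] == RP:
                    del lth[j + 1], llt[j + 1], lrt[j + 1]
                if j - 1 >= 0 and llt[j] == RP:
                    del lth[j], llt[j], lrt[j]
            else:
                off = rng.uniform(0.0, wseg - cd)
                a0 = lth[j] + off / state.r
                a1 = a0 + cd / state.r
                lth[j + 1:j + 1] = [a0, a1]
                llt[j + 1:j + 1] = [RM, RP]
                lrt[j + 1:j + 1] = [RP, RM]
        changes[int(lid)] = (lth, llt, lrt)
    _splice(state, changes)
    return state


def _splice(state: FrontState, changes: dict) -> None:
    """Rebuild the flat arrays with per-lineage replacement blocks."""
    th, li = state.theta, state.lin
    pieces_th, pieces_li, pieces_lt, pieces_rt = [], [], [], []
    cur = 0
    for lid in sorted(changes):
        a, b = np.searchsorted(li, [lid, lid + 1])
        if a > cur:
            pieces_th.append(th[cur:a])
            pieces_li.append(li[cur:a])
            pieces_lt.append(state.ltype[cur:a])
            pieces_rt.append(state.rtype[cur:a])
        nth, nlt, nrt = changes[lid]
        if nth:
            pieces_th.append(np.asarray(nth, dtype=float))
            pieces_li.append(np.full(len(nth), lid, dtype=np.int64))
            pieces_lt.append(np.asarray(nlt, dtype=np.int8))
            pieces_rt.append(np.asarray(nrt, dtype=np.int8))
        cur = b
    if cur < th.size:
        pieces_th.append(th[cur:])
        pieces_li.append(li[cur:])
        pieces_lt.append(state.ltype[cur:])
        pieces_rt.append(state.rtype[cur:])
    if pieces_th:
        state.theta = np.concatenate(pieces_th)
        state.lin = np.concatenate(pieces_li)
        state.ltype = np.concatenate(pieces_lt)
        state.rtype = np.concatenate(pieces_rt)
    else:
        state.theta = np.zeros(0)
        state.lin = np.zeros(0, dtype=np.int64)
        state.ltype = np.zeros(0, dtype=np.int8)
        state.rtype = np.zeros(0, dtype=np.int8)


# ---------------------------------------------------------------------------
# full simulation
# ---------------------------------------------------------------------------

def initial_front(config: RWConfig, rng: np.random.Generator) -> FrontState:
    """Place n0 single-segment R- clones with truncated-normal widths.

    Clones are independent non-interacting walker pairs; angular placement is
    uniform bookkeeping unless ``require_packing`` demands a without-overlap
    layout on the physical circle (a configuration error when infeasible).
    """
    widths = np.empty(config.n0)
    todo = np.arange(config.n0)
    while todo.size:
        draw = rng.normal(config.init_width_mean, config.init_width_sd, todo.size)
        widths[todo] = draw
        todo = todo[draw <= 0]
        todo = np.nonzero(widths <= 0)[0]
    ang_w = widths / config.r0
    if config.require_packing:
        total = ang_w.sum()
        if total >= 2 * math.pi:
            raise ValueError(
                f"cannot pack {config.n0} clones (total width {total * config.r0:.0f} μm) "
                f"on circumference {2 * math.pi * config.r0:.0f} μm"
            )
        gaps = rng.random(config.n0)
        gaps = gaps / gaps.sum() * (2 * math.pi - total)
        starts = np.cumsum(gaps) + np.r_[0.0, np.cumsum(ang_w[:-1])]
    else:
        starts = rng.uniform(0.0, 2 * math.pi, config.n0)

    theta = np.empty(2 * config.n0)
    theta[0::2] = starts
    theta[1::2] = starts + ang_w
    lin = np.repeat(np.arange(config.n0, dtype=np.int64), 2)
    lt = np.tile(np.array([WT, RM], dtype=np.int8), config.n0)
    rt = np.tile(np.array([RM, WT], dtype=np.int8), config.n0)
    return FrontState(config.r0, theta, lin, lt, rt)


def run_simulation(config: RWConfig) -> TrajectoryTable:
    """Run the boundary random walk from r0 to r_final.

    Iterates step → annihilate → nucleate, taking snapshots every
    ``snapshot_dr`` of radial growth (default: nine per run, the daily
    imaging cadence).  Returns the shared trajectory-table schema; ground
    truth (extinction radii, compensation events) goes into the metadata.
    """
    rng = np.random.default_rng(config.seed)
    state = initial_front(config, rng)
    snap_dr = config.snapshot_dr or (config.r_final - config.r0) / 8.0

    rows: list[tuple] = []
    _record(rows, state)
    next_snap = config.r0 + snap_dr
    n_steps = int(round((config.r_final - config.r0) / config.dr))
    for _ in range(n_steps):
        step_front(state, config, rng)
        annihilate_and_merge(state)
        nucleate_compensation(state, config, rng)
        if state.r >= next_snap - 1e-9:
            _record(rows, state)
            next_snap += snap_dr

    df = pd.DataFrame(rows, columns=SCHEMA)
    # lineage extinction radius = radius at which its last segment vanished
    extinct: dict[int, float] = {}
    alive = set(int(l) for l in state.lineage_ids())
    last_seen: dict[int, float] = {}
    for lid, _t, r in state.events:
        last_seen[int(lid)] = float(r)
    for lid, r in last_seen.items():
        if lid not in alive:
            extinct[lid] = r
    meta = {
        "generator": "rw_simulator",
        "config": asdict(config),
        "n0": config.n0,
        "extinction_r": extinct,
        "subclone_extinctions": [(int(l), _TYPE_STR[t], float(r)) for l, t, r in state.events],
    }
    return TrajectoryTable(df, meta)


def _record(rows: list, state: FrontState) -> None:
    for lid, t, th0, th1 in state.segments():
        rows.append((state.r, lid, _TYPE_STR[t], th0, th1, (th1 - th0) * state.r))


# ---------------------------------------------------------------------------
# deterministic width dynamics (D = 0 limit)
# ---------------------------------------------------------------------------

def width_drift(w, r, config: RWConfig, n_boundaries: int = 2):
    """Deterministic dw/dr = w/r − n_b·b(s(w)) for a single R- sector.

    A sector flanked by fitter neighbors on both sides has ``n_boundaries=2``
    inward-drifting walkers.
    """
    w = np.asarray(w, dtype=float)
    s = config.selection_coefficient(np.maximum(w, 0.0))
    return w / r - n_boundaries * bias_from_selection(s)


def equilibrium_width(r: float, config: RWConfig, w_max: float | None = None) -> float:
    """Stable root w* of w/r = b(s_eff(w)) at radius ``r``.

    For the logistic s_eff the drift is positive at small w (inflation wins),
    negative beyond w* (selection wins), positive again at very large w; the
    first sign change from + to − is the stable balance point.
    """
    from scipy.optimize import brentq

    if w_max is None:
        w_max = 2.0 * config.w_c
    ws = np.linspace(1e-3, w_max, 4000)
    d = width_drift(ws, r, config)
    sign_change = np.nonzero((d[:-1] > 0) & (d[1:] <= 0))[0]
    if sign_change.size == 0:
        raise ValueError("no stable equilibrium width in bracket")
    i = sign_change[0]
    return brentq(lambda w: width_drift(w, r, config), ws[i], ws[i + 1])


def integrate_width(w0: float, r0: float, r_final: float, config: RWConfig,
                    rtol: float = 1e-10, atol: float = 1e-12):
    """Integrate the deterministic width ODE; returns (r_grid, w(r))."""
    from scipy.integrate import solve_ivp

    sol = solve_ivp(
        lambda r, w: width_drift(max(w[0], 0.0), r, config),
        (r0, r_final), [w0], dense_output=True, rtol=rtol, atol=atol,
        max_step=(r_final - r0) / 100,
    )
    r = np.linspace(r0, r_final, 200)
    return r, sol.sol(r)[0]
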