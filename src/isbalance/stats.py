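"""Clone statistics over trajectory tables.

Implements the quantitative analyses applied identically to experimental-style
tables, random-walk runs and agent-based runs: lineage tracking across
snapshots, survival probabilities P_surv(r) = n(r)/n0 with Poisson counting
errors, the probability P_comp = n+/n0 of compensation-and-survival, the
rescue efficacy E = 1 − P_no-rescue / P_with-rescue with first-order error
propagation, treatment-failure summaries, clone-width series (median / IQR /
mean) and log-transformed kernel density estimates of width distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .tables import R_MINUS, R_PLUS, TrajectoryTable

__all__ = [
    "SurvivalCurve",
    "EfficacyCurve",
    "WidthDistribution",
    "FailureSummary",
    "track_clones",
    "survival_curve",
    "comp_probability",
    "efficacy",
    "failure_probability",
    "width_series",
    "kde_width_distribution",
]


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class SurvivalCurve:
    """P_surv(r) = n(r)/n0 on a radius grid, with Poisson σ = √n / n0."""

    r: np.ndarray
    n: np.ndarray
    n0: int

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        self.n = np.asarray(self.n, dtype=int)
        if np.any(np.diff(self.n) > 0):
            raise ValueError("lineage counts must be non-increasing in r")

    @property
    def p(self) -> np.ndarray:
        return self.n / self.n0

    @property
    def sigma(self) -> np.ndarray:
        return np.sqrt(self.n) / self.n0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"r_um": self.r, "n": self.n, "p_surv": self.p, "sigma": self.sigma})


@dataclass
class EfficacyCurve:
    """E(r) = 1 − P_no/P_with with propagated σ; NaN where P_with = 0."""

    r: np.ndarray
    e: np.ndarray
    sigma: np.ndarray
    window_of_inefficacy: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"r_um": self.r, "efficacy": self.e, "sigma": self.sigma})


@dataclass
class WidthDistribution:
    """Back-transformed log-KDE density on a width grid; f(0) = 0."""

    w: np.ndarray
    density: np.ndarray
    bandwidth: float
    pixel_cutoff: float
    snapshot_r: float | None = None

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.w))

    def __call__(self, w):
        return np.interp(w, self.w, self.density, left=0.0, right=0.0)


@dataclass
class FailureSummary:
    """Treatment-failure probability P_fail = N_fail/n0 at a treatment radius."""

    treatment_r: float
    n_fail: int
    n0: int
    n_compensated: int

    @property
    def p_fail(self) -> float:
        return self.n_fail / self.n0

    @property
    def sigma(self) -> float:
        return np.sqrt(self.n_fail) / self.n0

    @property
    def compensated_fraction(self) -> float:
        return self.n_compensated / self.n_fail if self.n_fail else np.nan

    @property
    def uncompensated_fraction(self) -> float:
        return 1.0 - self.compensated_fraction if self.n_fail else np.nan


# ---------------------------------------------------------------------------
# lineage tracking
# ---------------------------------------------------------------------------

def _circdist(a, b):
    d = np.abs(a - b) % (2 * np.pi)
    return np.minimum(d, 2 * np.pi - d)


def _group_arcs(snap: pd.DataFrame, join_tol: float):
    """Cluster a snapshot's arcs into contiguous clone groups (wrap-aware).

    Returns (group index per row, group circular centroid, group interval
    list) with centroids computed as width-weighted circular means.
    """
    idx = np.argsort(snap["theta_start_rad"].to_numpy())
    th0 = snap["theta_start_rad"].to_numpy()[idx]
    th1 = snap["theta_end_rad"].to_numpy()[idx]
    n = len(idx)
    gid = np.zeros(n, dtype=int)
    g = 0
    for k in range(1, n):
        if th0[k] - th1[k - 1] > join_tol:
            g += 1
        gid[k] = g
    # wrap-around: last group touches first across 0/2π
    if n > 1 and g > 0 and (th0[0] + 2 * np.pi) - th1[-1] <= join_tol:
        gid[gid == g] = 0
    groups = np.unique(gid)
    cent = np.empty(groups.size)
    for j, gg in enumerate(groups):
        m = gid == gg
        mid = 0.5 * (th0[m] + th1[m])
        wts = th1[m] - th0[m]
        wts = np.where(wts > 0, wts, 1e-12)
        cent[j] = np.arctan2(
            np.sum(wts * np.sin(mid)), np.sum(wts * np.cos(mid))
        ) % (2 * np.pi)
    # map back to original row order
    row_group = np.empty(n, dtype=int)
    remap = {gg: j for j, gg in enumerate(groups)}
    for k in range(n):
        row_group[idx[k]] = remap[gid[k]]
    intervals = [
        list(zip(th0[gid == gg], th1[gid == gg])) for gg in groups
    ]
    return row_group, cent, intervals


def track_clones(table: TrajectoryTable, gate: float = 0.05,
                 join_tol: float = 1e-6) -> TrajectoryTable:
    """Assign lineage ids by matching clone angular positions across snapshots.

    Greedy nearest-circular-centroid matching between consecutive snapshots
    within an angular ``gate`` (radians); unmatched previous clones are
    extinct, unmatched current clones are attached to an angularly
    overlapping parent (subclone emergence) or, failing that, start a new
    lineage.  Deterministic.
    """
    df = table.df.sort_values(["snapshot_r_um", "theta_start_rad"]).reset_index(drop=True)
    radii = np.unique(df["snapshot_r_um"])
    if radii.size < 2:
        raise ValueError("need at least two snapshots to track")
    lineage = np.full(len(df), -1, dtype=np.int64)

    prev_cent = None  # centroid per previous-snapshot lineage id
    next_id = 0
    for r in radii:
        rows = np.nonzero(df["snapshot_r_um"].to_numpy() == r)[0]
        snap = df.iloc[rows]
        if snap.duplicated(["theta_start_rad", "theta_end_rad"]).any():
            raise ValueError("duplicate angular intervals in one snapshot")
        row_group, cent, intervals = _group_arcs(snap, join_tol)
        assigned = np.full(cent.size, -1, dtype=np.int64)
        if prev_cent is None:
            for j in range(cent.size):
                assigned[j] = next_id
                next_id += 1
        else:
            prev_ids = np.array(sorted(prev_cent))
            pc = np.array([prev_cent[i] for i in prev_ids])
            # greedy: globally smallest distances first, one-to-one
            dmat = _circdist(cent[:, None], pc[None, :])
            order = np.argsort(dmat, axis=None)
            used_prev: set[int] = set()
            for flat in order:
                j, k = np.unravel_index(flat, dmat.shape)
                if dmat[j, k] > gate:
                    break
                if assigned[j] != -1 or int(prev_ids[k]) in used_prev:
                    continue
                assigned[j] = prev_ids[k]
                used_prev.add(int(prev_ids[k]))
            # unmatched current groups: attach to overlapping matched group
            for j in np.nonzero(assigned == -1)[0]:
                parent = -1
                for k in np.nonzero(assigned != -1)[0]:
                    if _circdist(cent[j], cent[k]) <= 2 * gate:
                        parent = assigned[k]
                        break
                if parent == -1:
                    parent = next_id
                    next_id += 1
                assigned[j] = parent
        lineage[rows] = assigned[row_group]
        prev_cent = {int(assigned[j]): cent[j] for j in range(cent.size)}

    out = df.copy()
    out["lineage_id"] = lineage
    meta = dict(table.meta)
    meta["tracked"] = True
    return TrajectoryTable(out, meta)


# ---------------------------------------------------------------------------
# survival / compensation / failure
# ---------------------------------------------------------------------------

def _counts_by_snapshot(table: TrajectoryTable) -> pd.Series:
    return table.df.groupby("snapshot_r_um")["lineage_id"].nunique()


def survival_curve(table: TrajectoryTable, r_grid=None) -> SurvivalCurve:
    """Count lineages with any surviving front segment at each radius.

    ``r_grid`` defaults to the snapshot radii; a custom grid is evaluated as
    a step function (last snapshot at or below each point) and must lie
    inside the table's radius range.
    """
    counts = _counts_by_snapshot(table)
    snap_r = counts.index.to_numpy()
    n0 = table.n0
    if r_grid is None:
        r_grid = snap_r
    r_grid = np.asarray(r_grid, dtype=float)
    cfg = table.meta.get("config", {}) if isinstance(table.meta, dict) else {}
    run_end = float(cfg.get("r_final", snap_r[-1]))
    if r_grid.min() < snap_r[0] - 1e-9:
        raise ValueError("r below the table's first snapshot")
    if r_grid.max() > run_end + 1e-6:
        raise ValueError("r beyond the simulated radius range")
    n = np.empty(r_grid.size, dtype=int)
    for i, r in enumerate(r_grid):
        j = np.searchsorted(snap_r, r + 1e-9) - 1
        # snapshots where every lineage is extinct emit no rows: grid points
        # past the last populated snapshot (but inside the run) count zero
        n[i] = 0 if r > snap_r[-1] + 1e-9 else counts.iloc[j]
    return SurvivalCurve(r_grid, n, n0)


def comp_probability(table: TrajectoryTable):
    """P_comp = n+/n0: lineages compensated *and* alive at the final radius.

    Returns ``(p, sigma)`` with Poisson σ = √n+ / n0.
    """
    cfg = table.meta.get("config", {}) if isinstance(table.meta, dict) else {}
    rf = table.r_final
    if float(cfg.get("r_final", rf)) > rf + 1e-6:
        return 0.0, 0.0  # run continued past the last populated snapshot: all extinct
    snap = table.at_radius(rf)
    nplus = snap.loc[snap["subclone_type"] == R_PLUS, "lineage_id"].nunique()
    n0 = table.n0
    return nplus / n0, np.sqrt(nplus) / n0


def efficacy(no_rescue, with_rescue):
    """Rescue efficacy E = 1 − P^no-rescue / P^with-rescue.

    Accepts two :class:`SurvivalCurve` on matching grids (returns an
    :class:`EfficacyCurve`) or two :class:`FailureSummary` (returns
    ``(E, sigma)``).  Poisson errors propagate to first order; points with
    zero with-rescue probability are flagged NaN.  The window of inefficacy
    is the largest grid radius at which |E| ≤ σ_E.
    """
    if isinstance(no_rescue, FailureSummary):
        pn, sn = no_rescue.p_fail, no_rescue.sigma
        pw, sw = with_rescue.p_fail, with_rescue.sigma
        if pw == 0:
            return np.nan, np.nan
        e = 1.0 - pn / pw
        sigma = np.hypot(sn / pw, pn * sw / pw**2)
        return e, sigma

    if not np.allclose(no_rescue.r, with_rescue.r):
        raise ValueError("survival curves must share a radius grid")
    pn, pw = no_rescue.p, with_rescue.p
    sn, sw = no_rescue.sigma, with_rescue.sigma
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(pw > 0, 1.0 - pn / pw, np.nan)
        sigma = np.where(pw > 0, np.hypot(sn / pw, pn * sw / pw**2), np.nan)
    ok = pw > 0
    inside = ok & (np.abs(e) <= sigma)
    window = float(no_rescue.r[inside].max()) if np.any(inside) else float(no_rescue.r[0])
    return EfficacyCurve(no_rescue.r.copy(), e, sigma, window)


def failure_probability(table: TrajectoryTable, treatment_r: float) -> FailureSummary:
    """Prospective treatment failure at ``treatment_r``.

    Every lineage still at the front when the drug is applied seeds one
    resurgent growth dome; regrowth itself is not simulated.  A dome counts
    as compensated if the lineage carries any R+ front segment then.
    """
    counts = _counts_by_snapshot(table)
    snap_r = counts.index.to_numpy()
    if treatment_r < snap_r[0] - 1e-9:
        raise ValueError("treatment radius before the first snapshot")
    j = np.searchsorted(snap_r, treatment_r + 1e-9) - 1
    r_use = snap_r[j]
    snap = table.df[table.df["snapshot_r_um"] == r_use]
    survivors = snap["lineage_id"].unique()
    ncomp = snap.loc[snap["subclone_type"] == R_PLUS, "lineage_id"].nunique()
    return FailureSummary(float(treatment_r), len(survivors), table.n0, int(ncomp))


# ---------------------------------------------------------------------------
# width statistics
# ---------------------------------------------------------------------------

def width_series(table: TrajectoryTable, subclone_type: str = R_MINUS,
                 exclude_mixed: bool = False,
                 plateau_range: tuple[float, float] | None = None):
    """Per-snapshot median / IQR / mean front clone widths of one type.

    A clone's width of a given type is the summed arc length of its segments
    of that type at the snapshot.  With ``exclude_mixed`` lineages carrying
    both types at a snapshot are dropped (the experimental convention for
    ambiguous segmentation); simulated subclones are otherwise considered
    independently.  Quartiles use linear (midpoint) interpolation.

    Returns ``(frame, equilibrium)`` where frame has columns
    ``r_um, n, median, q25, q75, mean`` and ``equilibrium`` is the median of
    per-snapshot medians over ``plateau_range`` (default: upper half of the
    radius range) together with its IQR-derived spread.
    """
    df = table.df
    per = df.groupby(["snapshot_r_um", "lineage_id", "subclone_type"])["width_um"].sum()
    per = per.reset_index()
    if exclude_mixed:
        ntypes = per.groupby(["snapshot_r_um", "lineage_id"])["subclone_type"].transform("nunique")
        per = per[ntypes == 1]
    sel = per[per["subclone_type"] == subclone_type]
    rows = []
    for r, grp in sel.groupby("snapshot_r_um"):
        w = grp["width_um"].to_numpy()
        if w.size == 0:
            continue  # gap, not zero
        q25, med, q75 = np.percentile(w, [25, 50, 75], method="linear")
        rows.append((r, w.size, med, q25, q75, w.mean()))
    frame = pd.DataFrame(rows, columns=["r_um", "n", "median", "q25", "q75", "mean"])
    if frame.empty:
        return frame, (np.nan, np.nan)
    radii = table.snapshot_radii
    if plateau_range is None:
        plateau_range = (0.5 * (radii[0] + radii[-1]), radii[-1])
    m = (frame["r_um"] >= plateau_range[0]) & (frame["r_um"] <= plateau_range[1])
    if m.any():
        w_eq = float(frame.loc[m, "median"].median())
        spread = float((frame.loc[m, "q75"] - frame.loc[m, "q25"]).median() / 2)
    else:
        w_eq, spread = np.nan, np.nan
    return frame, (w_eq, spread)


def kde_width_distribution(widths, bandwidth_rule="silverman",
                           pixel_cutoff: float = 0.0, grid=None,
                           snapshot_r: float | None = None) -> WidthDistribution:
    """Log-transformed Gaussian KDE of a clone-width sample.

    The KDE is built on ln(w) (bandwidth by Silverman's rule on the log
    scale unless a numeric factor is given) and back-transformed as
    f(w) = g(ln w)/w, which is supported on strictly positive widths and
    vanishes at w = 0.  Observations below ``pixel_cutoff`` (the one-pixel
    segmentation cut-off) are discarded first.
    """
    w = np.asarray(widths, dtype=float)
    w = w[w >= max(pixel_cutoff, 0.0)]
    w = w[w > 0]
    if w.size < 2:
        raise ValueError("need at least two positive widths after the cut-off")
    logs = np.log(w)
    kde = gaussian_kde(logs, bw_method=bandwidth_rule)
    if grid is None:
        lo = np.exp(logs.min() - 5 * kde.factor * max(logs.std(), 1e-3))
        hi = np.exp(logs.max() + 5 * kde.factor * max(logs.std(), 1e-3))
        grid = np.r_[0.0, np.geomspace(max(lo, 1e-12), hi, 1023)]
    grid = np.asarray(grid, dtype=float)
    dens = np.zeros_like(grid)
    pos = grid > 0
    dens[pos] = kde(np.log(grid[pos])) / grid[pos]
    return WidthDistribution(grid, dens, float(kde.factor), float(pixel_cutoff), snapshot_r)
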