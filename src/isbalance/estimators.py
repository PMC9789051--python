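"""Parameter estimation and the escape analysis.

Mutation rate from front-frequency decay
    Under neutrality of the compensated type, the front frequency of the
    uncompensated (red) type decays with colony radius as
    f_red(r) = f_red(r0)·exp(−μ(r−r0)), i.e.

        f_blue(r) = 1 − f_red(r0) · e^{μ (r0 − r)}.

    Fitted by orthogonal distance regression (errors on both axes), r0 fixed
    to the first measured radius, yielding μ per μm of radial growth.

Fitness cost from opening angles
    A faster sector's full opening angle expands logarithmically under the
    equal-time construction, φ(r) = φ0 + 2·b·ln(r/r0) with b = sqrt(s(2+s))
    per boundary; the fitted slope is inverted to ŝ.

Escape analysis
    For compensation events triggered at radius r*, the mean compensated
    clone width grows linearly; the slope gives the expansion Δr_escape
    needed to reach the escape width (6 cells), and the escape probability
    P_escape within a fixed horizon combines with
    P_mutate(r) = 1 − (1−μ)^{w(r)} into P_total = P_escape · P_mutate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.odr as odr

from .tables import R_MINUS, R_PLUS, TrajectoryTable

__all__ = [
    "FrequencySeries",
    "OpeningAngleSeries",
    "EscapeAnalysis",
    "fit_mutation_rate",
    "fit_fitness_from_angles",
    "p_mutate",
    "escape_analysis",
]


# ---------------------------------------------------------------------------
# series containers
# ---------------------------------------------------------------------------

@dataclass
class FrequencySeries:
    """Front frequencies of red (uncompensated) vs blue (compensated) clones."""

    r: np.ndarray
    f_red: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        self.f_red = np.asarray(self.f_red, dtype=float)
        if np.any(np.diff(self.r) <= 0):
            raise ValueError("radii must be strictly increasing")
        if np.any((self.f_red < 0) | (self.f_red > 1)):
            raise ValueError("frequencies must lie in [0, 1]")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)

    @property
    def f_blue(self) -> np.ndarray:
        return 1.0 - self.f_red


@dataclass
class OpeningAngleSeries:
    """Opening angle φ(r) of a faster-growing sector at increasing radii."""

    r: np.ndarray
    phi: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        if np.any(np.diff(self.r) <= 0):
            raise ValueError("radii must be strictly increasing")
        if np.any((self.phi <= 0) | (self.phi >= 2 * np.pi)):
            raise ValueError("opening angles must lie in (0, 2π)")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)


@dataclass
class EscapeAnalysis:
    """Escape statistics for compensation triggered at radius r*."""

    r_star: float
    slope: float            # μm of width per μm of radial growth
    slope_sigma: float
    dr_escape: float        # expansion from r* needed to reach w_escape
    p_escape: float
    p_escape_sigma: float
    p_mutate: float
    p_total: float
    w_escape_cells: float
    n_clones: int
    n_excluded: int


# ---------------------------------------------------------------------------
# fitters
# ---------------------------------------------------------------------------

def fit_mutation_rate(series: FrequencySeries, sx: float = 1.0,
                      sy: float | None = None, f_red0: float | None = None):
    """Orthogonal-distance fit of μ from front-frequency decay.

    The one-parameter model fixes r0 to the first radius and f_red(r0) either
    to ``f_red0`` (e.g. 1 for a pure uncompensated inoculum, which avoids
    anchoring to a noisy first observation) or, by default, to the first
    measured red frequency.  ``sx``/``sy`` default the per-point
    uncertainties when the series carries none.  Returns ``(mu_hat, sigma)``
    in μm⁻¹; a series whose blue frequency decreases (impossible under the
    model) yields μ̂ = 0 with a warning rather than a failure.
    """
    r, fb = series.r, series.f_blue
    if r.size < 3:
        raise ValueError("need at least three points")
    r0 = r[0]
    fr0 = series.f_red[0] if f_red0 is None else float(f_red0)
    sy_arr = series.sigma if series.sigma is not None else np.full(r.size, sy or 1e-3)

    def model(beta, x):
        return 1.0 - fr0 * np.exp(beta[0] * (r0 - x))

    # log-linear initial guess, clipped to the physical branch
    with np.errstate(divide="ignore", invalid="ignore"):
        fr_end = max(1.0 - fb[-1], 1e-12)
        mu0 = max(np.log(max(fr0, 1e-12) / fr_end) / max(r[-1] - r0, 1e-12), 0.0)
    data = odr.RealData(r, fb, sx=np.full(r.size, sx), sy=sy_arr)
    out = odr.ODR(data, odr.Model(model), beta0=[mu0]).run()
    mu_hat, mu_sigma = float(out.beta[0]), float(out.sd_beta[0])
    if mu_hat < 0:
        warnings.warn("blue frequency decreases; returning mu = 0", RuntimeWarning)
        return 0.0, mu_sigma
    return mu_hat, mu_sigma


def fit_fitness_from_angles(series: OpeningAngleSeries, sx: float = 1.0,
                            sy: float | None = None):
    """Fit φ(r) = φ0 + 2·sqrt(s(2+s))·ln(r/r0) and invert to the fitness s.

    Returns ``(s_hat, sigma, sign)``; ``sign = -1`` flags a shrinking sector
    (the focal clone is the slower one), in which case ``s_hat`` is the
    magnitude of the fitted fitness difference.
    """
    r, phi = series.r, series.phi
    if r.size < 3:
        raise ValueError("need at least three points")
    x = np.log(r / r[0])
    sy_arr = series.sigma if series.sigma is not None else np.full(r.size, sy or 1e-3)

    def model(beta, lx):
        return beta[0] + beta[1] * lx

    m0 = np.polyfit(x, phi, 1)[0]
    data = odr.RealData(x, phi, sx=np.full(r.size, sx / np.maximum(r, 1e-12)), sy=sy_arr)
    out = odr.ODR(data, odr.Model(model), beta0=[phi[0], m0]).run()
    slope, slope_sigma = float(out.beta[1]), float(out.sd_beta[1])
    sign = -1 if slope < 0 else 1
    b = abs(slope) / 2.0
    s_hat = np.sqrt(1.0 + b * b) - 1.0
    # ds/db = b / sqrt(1+b²)
    s_sigma = (b / np.sqrt(1.0 + b * b)) * (slope_sigma / 2.0)
    return float(s_hat), float(s_sigma), sign


def p_mutate(w, mu):
    """P_mutate = 1 − (1−μ)^w for a clone w cells wide at the front.

    Real (non-integer) widths use the continuous power convention.
    """
    w = np.asarray(w, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any((mu < 0) | (mu > 1)):
        raise ValueError("mu must lie in [0, 1]")
    if np.any(w < 0):
        raise ValueError("width must be non-negative")
    out = 1.0 - np.power(1.0 - mu, w)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# escape analysis over triggered ensembles
# ---------------------------------------------------------------------------

def escape_analysis(tables, r_star: float, mu_per_step: float,
                    w_escape_cells: float = 6.0, horizon: float = 2500.0,
                    cell_diameter: float = 12.0,
                    w_init: float | None = None) -> EscapeAnalysis:
    """Escape statistics for an ensemble of runs triggered at the same r*.

    Per run, every lineage carrying R+ front segments after r* is a
    triggered clone; runs with no uncompensated clone alive at r* are
    excluded from the denominator.  The mean compensated width vs radius is
    fitted linearly from r*; Δr_escape = (w_escape − w_init)/slope with
    ``w_init`` one cell diameter (the nucleus size).  P_escape is the
    fraction of triggered clones whose compensated width exceeds the escape
    width within ``horizon`` μm of further expansion, and
    P_total = P_escape · P_mutate(w̄(r*)) exactly.
    """
    w_escape_um = w_escape_cells * cell_diameter
    if w_init is None:
        w_init = cell_diameter
    widths_at = {}      # radius -> list of compensated widths
    n_triggered = 0
    n_escaped = 0
    n_excluded = 0
    w_rstar = []        # uncompensated clone widths (cells) at r*
    for tab in tables:
        df = tab.df
        radii = np.unique(df["snapshot_r_um"])
        r_at = radii[radii >= r_star - 1e-6]
        pre = df[(df["snapshot_r_um"] == (r_at[0] if r_at.size else radii[-1]))
                 & (df["subclone_type"] == R_MINUS)]
        if pre.empty:
            n_excluded += 1
            continue
        w_rstar.extend(pre.groupby("lineage_id")["width_um"].sum() / cell_diameter)
        post = df[(df["snapshot_r_um"] >= r_star - 1e-6)
                  & (df["snapshot_r_um"] <= r_star + horizon + 1e-6)
                  & (df["subclone_type"] == R_PLUS)]
        comp = post.groupby(["snapshot_r_um", "lineage_id"])["width_um"].sum()
        lineages = comp.index.get_level_values("lineage_id").unique()
        n_triggered += len(lineages)
        for lid in lineages:
            traj = comp.xs(lid, level="lineage_id")
            if traj.max() > w_escape_um:
                n_escaped += 1
        for (r, _lid), w in comp.items():
            widths_at.setdefault(float(r), []).append(float(w))

    if n_triggered == 0:
        raise ValueError("no triggered clones in the ensemble")
    rs = np.array(sorted(widths_at))
    means = np.array([np.mean(widths_at[r]) for r in rs])
    if rs.size > 2:
        coef, cov = np.polyfit(rs, means, 1, cov=True)
        slope, slope_sigma = float(coef[0]), float(np.sqrt(cov[0, 0]))
    elif rs.size == 2:
        slope = float(np.polyfit(rs, means, 1)[0])
        slope_sigma = np.nan
    else:
        slope, slope_sigma = np.nan, np.nan
    dr_escape = (w_escape_um - w_init) / slope if slope > 0 else np.inf
    p_esc = n_escaped / n_triggered
    p_esc_sigma = np.sqrt(max(n_escaped, 1)) / n_triggered
    p_mut = float(p_mutate(np.mean(w_rstar), mu_per_step))
    return EscapeAnalysis(
        r_star=float(r_star), slope=slope, slope_sigma=slope_sigma,
        dr_escape=float(dr_escape), p_escape=p_esc, p_escape_sigma=p_esc_sigma,
        p_mutate=p_mut, p_total=p_esc * p_mut,
        w_escape_cells=float(w_escape_cells), n_clones=n_triggered,
        n_excluded=n_excluded,
    )
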