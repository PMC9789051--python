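"""Boundary-random-walk model: elementary relations, single steps, dynamics."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from isbalance.rw import (
    RM,
    RP,
    WT,
    FrontState,
    RWConfig,
    annihilate_and_merge,
    bias_from_selection,
    effective_selection,
    equilibrium_width,
    initial_front,
    integrate_width,
    nucleate_compensation,
    run_simulation,
    step_front,
    width_drift,
)


# ---------------------------------------------------------------------------
# elementary relations
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "s, expected",
    [
        (0.0, 0.0),                      # neutral boundary does not drift
        (0.013, 0.1617683529),           # sqrt(0.013 * 2.013)
        (0.21, 0.6812488533),            # sqrt(0.21 * 2.21)
    ],
)
def test_bias_from_selection_values(s, expected):
    assert bias_from_selection(s) == pytest.approx(expected, rel=1e-8)


def test_bias_rejects_negative_without_flag():
    with pytest.raises(ValueError):
        bias_from_selection(-0.013)
    assert bias_from_selection(-0.013, absolute=True) == pytest.approx(
        math.sqrt(0.013 * (2 - 0.013))
    )


def test_bias_monotone_in_s():
    s = np.linspace(0, 1, 50)
    b = bias_from_selection(s)
    assert np.all(np.diff(b) > 0)


def test_effective_selection_limits_and_value():
    # saturates to the bare cost, vanishes at zero width
    assert effective_selection(1e12, 0.013, 280.0) == pytest.approx(0.013, rel=1e-9)
    assert effective_selection(0.0, 0.013, 280.0) == 0.0
    # at w = w_c the logistic gives 2 s0 / (1 + e)
    assert effective_selection(280.0, 0.013, 280.0) == pytest.approx(
        2 * 0.013 / (1 + math.e), rel=1e-12
    )
    w = np.linspace(1.0, 2000.0, 400)
    se = effective_selection(w, 0.013, 280.0)
    assert np.all(np.diff(se) > 0)
    with pytest.raises(ValueError):
        effective_selection(-1.0, 0.013, 280.0)


# ---------------------------------------------------------------------------
# single steps
# ---------------------------------------------------------------------------

def _single_clone_state(r0=1500.0, w0=20.0, typ=RM, th0=1.0):
    return FrontState.from_segments(r0, [(th0, th0 + w0 / r0, typ, 0)])


def test_step_neutral_no_noise_is_pure_inflation():
    cfg = RWConfig(s0=0.0, D=0.0, mu=0.0, n0=1)
    state = _single_clone_state()
    th_before = state.theta.copy()
    rng = np.random.default_rng(0)
    for _ in range(100):
        step_front(state, cfg, rng)
    assert np.allclose(state.theta, th_before)  # angles frozen
    (lid, t, a0, a1), = list(state.segments())
    assert (a1 - a0) * state.r == pytest.approx(20.0 * state.r / 1500.0)


def test_step_variance_matches_4_D_dr():
    """Empirical per-step lateral variance of neutral boundaries is 4·D·dr."""
    cfg = RWConfig(s0=0.0, D=0.23, mu=0.0, n0=1, dr=1.0)
    n = 10**5
    th = np.linspace(0.1, 2 * math.pi - 0.1, 2 * n)
    lin = np.repeat(np.arange(n), 2)
    lt = np.tile(np.array([WT, RM], dtype=np.int8), n)
    rt = np.tile(np.array([RM, WT], dtype=np.int8), n)
    state = FrontState(1500.0, th.copy(), lin, lt, rt)
    step_front(state, cfg, np.random.default_rng(42))
    arc = (state.theta - th) * (1500.0 + 0.5)
    assert arc.var() == pytest.approx(4 * 0.23 * 1.0, rel=0.02)
    assert arc.mean() == pytest.approx(0.0, abs=3 * math.sqrt(0.92 / (2 * n)))


def test_constant_selection_closed_form_width():
    """D = 0: both boundaries drift inward at b, so the angular width falls as
    w/r = w0/r0 − 2·b·ln(r/r0); a single boundary follows x/r = x0/r0 − b·ln(r/r0)."""
    s, r0, w0 = 0.013, 1500.0, 400.0
    b = bias_from_selection(s)
    for dr in (1.0, 0.1):
        cfg = RWConfig(s0=s, D=0.0, mu=0.0, n0=1, selection_mode="null",
                       dr=dr, r_final=3000.0)
        state = _single_clone_state(r0, w0)
        th_left0 = state.theta[0]
        rng = np.random.default_rng(0)
        nsteps = int(round(1500.0 / dr))
        for _ in range(nsteps):
            step_front(state, cfg, rng)
        r = state.r
        got = state.theta[1] - state.theta[0]           # angular width
        expect = w0 / r0 - 2 * b * math.log(r / r0)
        assert got == pytest.approx(expect, rel=1e-6)
        # per-boundary logarithmic drift (the equal-time single-walker form)
        got_left = state.theta[0] - th_left0
        assert got_left == pytest.approx(b * math.log(r / r0), rel=1e-6)


def test_width_dependent_trajectory_matches_ode():
    """D = 0 width-dependent trajectory converges (first order in dr) to the
    integrated deterministic ODE dw/dr = w/r − 2·b(s_eff(w)); at dr/10 the
    refined trajectory agrees to better than 1e-6 relative error."""
    r_end = 1800.0
    _, w_ode = integrate_width(60.0, 1500.0, r_end, RWConfig(D=0.0, mu=0.0, n0=1))
    for dr, rtol in ((0.1, 1e-5), (0.01, 1e-6)):
        cfg = RWConfig(D=0.0, mu=0.0, n0=1, dr=dr, r_final=r_end)
        state = _single_clone_state(1500.0, 60.0)
        rng = np.random.default_rng(0)
        for _ in range(int(round((r_end - 1500.0) / dr))):
            step_front(state, cfg, rng)
        w_sim = (state.theta[1] - state.theta[0]) * state.r
        assert w_sim == pytest.approx(w_ode[-1], rel=rtol)


# ---------------------------------------------------------------------------
# annihilation and merging
# ---------------------------------------------------------------------------

def test_annihilate_identity_without_crossing():
    state = _single_clone_state()
    before = state.theta.copy()
    annihilate_and_merge(state)
    assert np.array_equal(state.theta, before)
    assert state.events == []


def test_annihilate_middle_segment_merges_flanks():
    """A collapsed R- clone between wild-type flanks disappears entirely."""
    state = _single_clone_state(1500.0, 20.0)
    state.theta = state.theta[::-1].copy()  # force the crossing
    annihilate_and_merge(state)
    assert state.n_boundaries == 0
    assert state.lineage_ids().size == 0
    assert state.events == [(0, RM, 1500.0)]


def test_annihilate_rm_rp_rm_leaves_neutral_rp():
    """When both R- flanks of a compensated subclone die, the surviving R+
    segment borders wild type on both sides."""
    r = 1500.0
    state = FrontState.from_segments(
        r,
        [(1.00, 1.01, RM, 0), (1.01, 1.02, RP, 0), (1.02, 1.03, RM, 0)],
    )
    # cross both R- segments' boundary pairs
    th = state.theta.copy()
    th[0], th[1] = th[1] + 1e-4, th[0]        # left R- collapses
    th[2], th[3] = th[3], th[2] - 1e-4        # right R- collapses
    state.theta = th
    annihilate_and_merge(state)
    segs = list(state.segments())
    assert len(segs) == 1
    lid, t, a0, a1 = segs[0]
    assert t == RP
    assert state.ltype[0] == WT and state.rtype[-1] == WT
    assert sorted(e[1] for e in state.events) == [RM, RM]


# ---------------------------------------------------------------------------
# compensation nucleation
# ---------------------------------------------------------------------------

def test_no_mutation_at_zero_rate():
    cfg = RWConfig(mu=0.0, n0=1)
    state = _single_clone_state()
    rng = np.random.default_rng(1)
    for _ in range(200):
        nucleate_compensation(state, cfg, rng)
    assert all(t == RM for _, t, _, _ in state.segments())


def test_mutation_rate_first_order():
    """Expected nucleations per step ≈ μ·(w/cell)·dr in the rare regime."""
    mu, w, cd, dr = 1e-3, 60.0, 12.0, 1.0
    cfg = RWConfig(mu=mu, cell_diameter=cd, dr=dr, n0=1)
    p_expect = mu * (w / cd) * dr
    n = 40000
    rng = np.random.default_rng(3)
    hits = 0
    th0 = np.linspace(0.1, 2 * math.pi, n)
    lin = np.repeat(np.arange(n), 2)
    lt = np.tile(np.array([WT, RM], dtype=np.int8), n)
    rt = np.tile(np.array([RM, WT], dtype=np.int8), n)
    th = np.empty(2 * n)
    th[0::2] = th0
    th[1::2] = th0 + w / 1500.0
    state = FrontState(1500.0, th, lin, lt, rt)
    nucleate_compensation(state, cfg, rng)
    hits = sum(1 for _, t, _, _ in state.segments() if t == RP)
    se = math.sqrt(n * p_expect)
    assert abs(hits - n * p_expect) < 4 * se


def test_saturating_mutation_converts_whole_clone():
    """A two-cell clone at huge μ is fully compensated within one snapshot."""
    cfg = RWConfig(mu=10.0, D=0.0, s0=0.0, n0=1, cell_diameter=12.0)
    state = _single_clone_state(1500.0, 24.0)
    rng = np.random.default_rng(5)
    for _ in range(20):  # a fraction of one snapshot interval
        step_front(state, cfg, rng)
        annihilate_and_merge(state)
        nucleate_compensation(state, cfg, rng)
    types = {t for _, t, _, _ in state.segments()}
    assert types == {RP}


# ---------------------------------------------------------------------------
# full runs: invariants
# ---------------------------------------------------------------------------

def test_single_neutral_clone_survives_with_exact_inflation():
    cfg = RWConfig(n0=1, D=0.0, s0=0.0, mu=0.0, seed=0)
    tab = run_simulation(cfg)
    final = tab.at_radius(tab.r_final)
    assert len(final) == 1
    w0 = tab.at_radius(1500.0)["width_um"].iloc[0]
    assert final["width_um"].iloc[0] == pytest.approx(w0 * tab.r_final / 1500.0)


def test_neutral_width_martingale():
    """With s = 0 the expected angular clone width is conserved (z-test)."""
    n = 10000
    cfg = RWConfig(n0=n, s0=0.0, mu=0.0, seed=21, r_final=1700.0,
                   snapshot_dr=200.0, init_width_mean=40.0, init_width_sd=5.0)
    tab = run_simulation(cfg)
    df = tab.df
    first = df[df.snapshot_r_um == 1500.0]
    last = df[df.snapshot_r_um == 1700.0]
    ang0 = (first["theta_end_rad"] - first["theta_start_rad"])
    # extinct clones contribute zero angular width to the ensemble mean
    ang1 = (last["theta_end_rad"] - last["theta_start_rad"])
    mean0 = ang0.sum() / n
    mean1 = ang1.sum() / n
    # conservative bound on the SE of the change: per-boundary variance of
    # the accumulated noise over 200 μm at r ≈ 1500
    var_step = 2 * 4 * 0.23 * 200.0 / 1500.0**2
    se = math.sqrt(var_step / n) * 3  # inflate: absorption correlations
    z = (mean1 - mean0) / se
    assert abs(z) < 2.58  # α = 0.01


def test_survival_counts_non_increasing(rw_small_table):
    df = rw_small_table.df
    counts = df.groupby("snapshot_r_um")["lineage_id"].nunique()
    assert np.all(np.diff(counts.to_numpy()) <= 0)


def test_segment_bookkeeping_consistency(rw_small_table):
    """Per snapshot: extents non-negative, widths = Δθ·r, no same-type
    adjacency within a lineage (post-merge invariant)."""
    rw_small_table.validate()
    df = rw_small_table.df
    for (_r, _lid), grp in df.groupby(["snapshot_r_um", "lineage_id"]):
        grp = grp.sort_values("theta_start_rad")
        assert (grp["width_um"] >= 0).all()
        types = grp["subclone_type"].to_list()
        starts = grp["theta_start_rad"].to_numpy()
        ends = grp["theta_end_rad"].to_numpy()
        contiguous = np.isclose(starts[1:], ends[:-1])
        for k in range(len(types) - 1):
            if contiguous[k]:
                assert types[k] != types[k + 1]


def test_packed_front_conservation_and_placement_error():
    """Packed placement covers 2π exactly (typed + wild-type gaps) and an
    impossible packing is a configuration error."""
    cfg = RWConfig(n0=50, require_packing=True, seed=2, D=0.0, s0=0.0, mu=0.0)
    rng = np.random.default_rng(2)
    state = initial_front(cfg, rng)
    covered = 0.0
    th = state.theta
    for i in range(0, th.size, 2):
        covered += th[i + 1] - th[i]                     # clone extents
    gaps = 0.0
    for i in range(1, th.size - 1, 2):
        gaps += th[i + 1] - th[i]                        # wild-type gaps
    gaps += 2 * math.pi - (th[-1] - th[0])               # wrap-around gap
    assert covered + gaps == pytest.approx(2 * math.pi, abs=1e-9)

    with pytest.raises(ValueError, match="pack"):
        initial_front(RWConfig(n0=10000, require_packing=True), rng)


# ---------------------------------------------------------------------------
# fixed point of the width-dependent ODE
# ---------------------------------------------------------------------------

def test_stable_fixed_point_and_convergence():
    """Inflation-selection balance: the width ODE has a stable root w* and
    ±20% perturbations relax back toward the (slowly moving) equilibrium."""
    cfg = RWConfig(D=0.0, mu=0.0, n0=1)
    r_ref = 6000.0
    w_star = equilibrium_width(r_ref, cfg)
    assert 5.0 < w_star < 280.0
    eps = 1e-3
    slope = (width_drift(w_star + eps, r_ref, cfg)
             - width_drift(w_star - eps, r_ref, cfg)) / (2 * eps)
    assert slope < 0  # restoring

    for f in (0.8, 1.2):
        r_grid, w = integrate_width(f * w_star, r_ref, 9000.0, cfg)
        w_eq_end = equilibrium_width(9000.0, cfg)
        assert abs(w[-1] - w_eq_end) < abs(f * w_star - w_star) * 0.5


# ---------------------------------------------------------------------------
# oracle equivalence on a small instance
# ---------------------------------------------------------------------------

def _oracle_two_walker(n_runs, r0, r_final, dr, w0, b, D, seed):
    """Independent brute-force reference: one clone = two arc-space walkers.

    Returns (extinction radii (NaN if alive), widths at r_final of the
    survivors).
    """
    rng = np.random.default_rng(seed)
    ext = np.full(n_runs, np.nan)
    widths = []
    for k in range(n_runs):
        left, right = 0.0, w0 / r0  # angular coordinates
        r = r0
        while r < r_final:
            rm = r + 0.5 * dr
            left += rng.normal(b * dr, math.sqrt(4 * D * dr)) / rm
            right += rng.normal(-b * dr, math.sqrt(4 * D * dr)) / rm
            r += dr
            if right <= left:
                ext[k] = r
                break
        else:
            widths.append((right - left) * r)
    return ext, np.asarray(widths)


def test_single_clone_statistics_match_bruteforce_oracle():
    """Extinction-radius distribution and surviving widths of the engine agree
    with an independently coded one-clone reference (KS tests, α = 0.01)."""
    n = 3000
    r0, r_final, dr, w0 = 1500.0, 2100.0, 1.0, 30.0
    s, D = 0.0005, 0.23  # weak cost: both fates well represented
    cfg = RWConfig(s0=s, D=D, mu=0.0, n0=n, selection_mode="null",
                   r0=r0, r_final=r_final, dr=dr, snapshot_dr=600.0,
                   init_width_mean=w0, init_width_sd=1e-9, seed=13)
    tab = run_simulation(cfg)
    ext_pkg = np.array(list(tab.meta["extinction_r"].values()), dtype=float)
    last = tab.df[tab.df.snapshot_r_um == r_final]
    w_pkg = last.groupby("lineage_id")["width_um"].sum().to_numpy()

    b = bias_from_selection(s)
    ext_orc, w_orc = _oracle_two_walker(n, r0, r_final, dr, w0, b, D, seed=99)
    ext_orc = ext_orc[~np.isnan(ext_orc)]

    # survival fractions agree within binomial error
    p1, p2 = w_pkg.size / n, w_orc.size / n
    se = math.sqrt(p1 * (1 - p1) / n + p2 * (1 - p2) / n)
    assert abs(p1 - p2) < 3 * max(se, 1e-3)
    assert sps.ks_2samp(ext_pkg, ext_orc).pvalue > 0.01
    assert sps.ks_2samp(w_pkg, w_orc).pvalue > 0.01
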