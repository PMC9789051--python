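"""Synthetic inputs with the statistical structure of the imaging pipeline.

The experimental pipeline produces per-day clone trajectory tables from
segmented fluorescence images.  This module emulates those outputs — daily
radius snapshots, angular position noise, pixel-size width quantization,
withheld lineage identities — with known ground truth, so that the tracking
and statistics layers can be validated end to end without any imaging data.
Forward models for the mutation-rate and fitness assays are included.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np
import pandas as pd

from .estimators import FrequencySeries, OpeningAngleSeries
from .rw import RWConfig, bias_from_selection, run_simulation
from .tables import R_MINUS, SCHEMA, TrajectoryTable

__all__ = [
    "SynthConfig",
    "ScriptedClone",
    "generate_trajectory_table",
    "generate_frequency_series",
    "generate_opening_angles",
]


@dataclass
class ScriptedClone:
    """Explicit per-lineage script: width function (μm), lifetime, position."""

    center_rad: float
    width_fn: Callable[[float], float]
    birth_r: float | None = None
    extinction_r: float | None = None
    subclone_type: str = R_MINUS


@dataclass
class SynthConfig:
    """Scenario and noise model for synthetic trajectory tables.

    ``pixel_size`` (default 2 μm, a plausible microscope scale) quantizes
    widths; ``angular_noise_sd`` (radians) shifts whole arcs, emulating
    segmentation jitter.  Snapshots default to nine daily radial increments
    spanning r0 → r_final.
    """

    scenario: str = "neutral"  # neutral | constant_selection | width_dependent | scripted
    n_lineages: int = 50
    r0: float = 1500.0
    r_final: float = 7500.0
    snapshot_dr: float | None = None
    angular_noise_sd: float = 0.002
    pixel_size: float = 2.0
    mu: float = 0.0
    s0: float = 0.013
    w_c: float = 280.0
    D: float = 0.23
    init_width_mean: float = 20.0
    init_width_sd: float = 5.0
    seed: int = 0
    scripted: list[ScriptedClone] = field(default_factory=list)

    def __post_init__(self):
        if self.pixel_size < 0 or self.angular_noise_sd < 0:
            raise ValueError("noise parameters must be non-negative")
        if self.snapshot_dr is not None and self.snapshot_dr <= 0:
            raise ValueError("snapshot interval must be positive")


def generate_trajectory_table(config: SynthConfig):
    """Emit a measurement-like table and its ground truth.

    Returns ``(observed, truth)``: ``observed`` has lineage ids withheld
    (-1), angular positions perturbed and widths quantized; ``truth`` is the
    unperturbed table with true ids, row-aligned with ``observed``.  With
    zero noise and zero pixel size the two tables agree bit for bit (ids
    aside).
    """
    rng = np.random.default_rng(config.seed)
    snap_dr = config.snapshot_dr or (config.r_final - config.r0) / 8.0

    if config.scenario == "scripted":
        truth = _scripted_table(config, snap_dr)
    elif config.scenario in ("neutral", "constant_selection", "width_dependent"):
        mode = "width_dependent" if config.scenario == "width_dependent" else "null"
        s0 = 0.0 if config.scenario == "neutral" else config.s0
        rw_cfg = RWConfig(
            s0=s0, w_c=config.w_c, D=config.D, mu=config.mu,
            r0=config.r0, r_final=config.r_final, n0=config.n_lineages,
            init_width_mean=config.init_width_mean,
            init_width_sd=config.init_width_sd,
            selection_mode=mode, snapshot_dr=snap_dr,
            require_packing=True,  # clones start well-segregated, as inoculated
            seed=int(rng.integers(2**31 - 1)),
        )
        truth = run_simulation(rw_cfg)
    else:
        raise ValueError(f"unknown scenario {config.scenario!r}")

    df = truth.df.copy().reset_index(drop=True)
    obs = df.copy()
    obs["arc_id"] = np.arange(len(obs))  # segmentation-object id → truth row
    if config.angular_noise_sd > 0:
        shift = rng.normal(0.0, config.angular_noise_sd, len(obs))
        obs["theta_start_rad"] += shift
        obs["theta_end_rad"] += shift
    if config.pixel_size > 0:
        w = obs["width_um"].to_numpy()
        wq = np.round(w / config.pixel_size) * config.pixel_size
        obs["width_um"] = wq
        obs["theta_end_rad"] = obs["theta_start_rad"] + wq / obs["snapshot_r_um"]
        obs = obs[obs["width_um"] > 0].reset_index(drop=True)
    else:
        obs["width_um"] = (obs["theta_end_rad"] - obs["theta_start_rad"]) * obs["snapshot_r_um"]
    obs["lineage_id"] = -1

    meta = dict(truth.meta)
    meta.update(generator="synthetic_data", synth_config=_cfg_dict(config))
    truth = TrajectoryTable(df, dict(meta))
    observed = TrajectoryTable(obs, dict(meta))
    return observed, truth


def _scripted_table(config: SynthConfig, snap_dr: float) -> TrajectoryTable:
    radii = np.arange(config.r0, config.r_final + 1e-9, snap_dr)
    rows = []
    for lid, clone in enumerate(config.scripted):
        birth = clone.birth_r if clone.birth_r is not None else config.r0
        death = clone.extinction_r if clone.extinction_r is not None else np.inf
        for r in radii:
            if not (birth - 1e-9 <= r < death):
                continue
            w = float(clone.width_fn(r))
            if w <= 0:
                continue
            half = 0.5 * w / r
            rows.append((r, lid, clone.subclone_type,
                         clone.center_rad - half, clone.center_rad + half, w))
    df = pd.DataFrame(rows, columns=SCHEMA)
    # scripted clones must not overlap within a snapshot
    for r, snap in df.groupby("snapshot_r_um"):
        iv = snap.sort_values("theta_start_rad")
        if np.any(iv["theta_start_rad"].to_numpy()[1:] < iv["theta_end_rad"].to_numpy()[:-1]):
            raise ValueError(f"scripted clones overlap at r={r}")
    meta = {"n0": len(config.scripted), "config": {"r_final": config.r_final}}
    return TrajectoryTable(df, meta)


def generate_frequency_series(mu_true: float, r_grid, noise_sd: float = 0.0,
                              seed: int = 0, f_red0: float = 1.0) -> FrequencySeries:
    """Forward model of the mutation-rate assay: exponential red-clone decay.

    f_red(r) = f_red(r0)·exp(−μ(r−r0)) plus truncated Gaussian noise clipped
    to [0, 1]; the generating rate is recorded on the returned series.
    """
    if mu_true < 0:
        raise ValueError("mu_true must be non-negative")
    r = np.asarray(r_grid, dtype=float)
    f = f_red0 * np.exp(-mu_true * (r - r[0]))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        f = np.clip(f + rng.normal(0.0, noise_sd, r.size), 0.0, 1.0)
    series = FrequencySeries(r, f, np.full(r.size, max(noise_sd, 1e-4)))
    series.mu_true = mu_true  # ground truth annotation
    return series


def generate_opening_angles(s_true: float, r_grid, noise_sd: float = 0.0,
                            seed: int = 0, phi0: float = 0.1) -> OpeningAngleSeries:
    """Forward model of the fitness assay: logarithmic sector expansion.

    φ(r) = φ0 + 2·sqrt(s(2+s))·ln(r/r0) plus Gaussian noise.
    """
    if s_true < 0:
        raise ValueError("s_true must be non-negative")
    r = np.asarray(r_grid, dtype=float)
    phi = phi0 + 2.0 * bias_from_selection(s_true) * np.log(r / r[0])
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        phi = phi + rng.normal(0.0, noise_sd, r.size)
    series = OpeningAngleSeries(r, phi, np.full(r.size, max(noise_sd, 1e-4)))
    series.s_true = s_true
    return series


def _cfg_dict(config: SynthConfig) -> dict:
    d = asdict(config)
    d["scripted"] = len(config.scripted)  # callables are not serializable
    return d
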