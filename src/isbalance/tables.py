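"""Shared clone-trajectory table: the tidy per-snapshot, per-subclone dataset.

Every simulator and the synthetic generator emit the same schema so that the
statistics layer runs unchanged on any of them:

    snapshot_r_um   colony radius at the snapshot (μm)
    lineage_id      integer lineage identity (-1 when withheld)
    subclone_type   "R-" (uncompensated resistant) or "R+" (compensated)
    theta_start_rad angular start of the arc
    theta_end_rad   angular end of the arc
    width_um        arc length (theta_end - theta_start) * snapshot_r_um

A table travels with a metadata block (generating config, seed, ground-truth
extinction radii where known), serialized as a JSON sidecar next to the CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SCHEMA = [
    "snapshot_r_um",
    "lineage_id",
    "subclone_type",
    "theta_start_rad",
    "theta_end_rad",
    "width_um",
]

#: subclone type labels used throughout the package
R_MINUS = "R-"
R_PLUS = "R+"


@dataclass
class TrajectoryTable:
    """A tidy clone-trajectory dataset plus provenance metadata."""

    df: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in SCHEMA if c not in self.df.columns]
        if missing:
            raise ValueError(f"trajectory table missing columns: {missing}")

    # -- convenience accessors -------------------------------------------
    @property
    def snapshot_radii(self) -> np.ndarray:
        return np.unique(self.df["snapshot_r_um"].to_numpy())

    @property
    def r_final(self) -> float:
        return float(self.df["snapshot_r_um"].max())

    @property
    def n0(self) -> int:
        """Initial lineage count (metadata if present, else first snapshot)."""
        if "n0" in self.meta:
            return int(self.meta["n0"])
        r0 = self.df["snapshot_r_um"].min()
        return int(self.df.loc[self.df["snapshot_r_um"] == r0, "lineage_id"].nunique())

    def at_radius(self, r: float, atol: float = 1e-6) -> pd.DataFrame:
        """Rows of the snapshot at radius ``r`` (must match a snapshot radius)."""
        radii = self.snapshot_radii
        i = int(np.argmin(np.abs(radii - r)))
        if abs(radii[i] - r) > atol:
            raise ValueError(f"no snapshot at r={r}; nearest is {radii[i]}")
        return self.df[self.df["snapshot_r_um"] == radii[i]]

    def validate(self, rtol: float = 1e-6) -> None:
        """Check width/angle consistency row by row."""
        w = (self.df["theta_end_rad"] - self.df["theta_start_rad"]) * self.df[
            "snapshot_r_um"
        ]
        if not np.allclose(w, self.df["width_um"], rtol=rtol, atol=1e-9):
            raise ValueError("width_um inconsistent with angular extent * radius")
        if (self.df["width_um"] < -1e-9).any():
            raise ValueError("negative widths present")

    # -- IO ---------------------------------------------------------------
    def write(self, csv_path: str | Path) -> None:
        csv_path = Path(csv_path)
        self.df.to_csv(csv_path, index=False)
        sidecar = csv_path.with_suffix(".json")
        with open(sidecar, "w") as fh:
            json.dump(_jsonable(self.meta), fh, indent=1)

    @classmethod
    def read(cls, csv_path: str | Path) -> "TrajectoryTable":
        csv_path = Path(csv_path)
        df = pd.read_csv(csv_path)
        sidecar = csv_path.with_suffix(".json")
        meta = {}
        if sidecar.exists():
            with open(sidecar) as fh:
                meta = json.load(fh)
        return cls(df, meta)


def _jsonable(obj):
    """Recursively convert numpy scalars/arrays for JSON serialization."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
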