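"""Shared fixtures: small canonical runs reused across test modules."""

import numpy as np
import pytest

from isbalance.abm import ABMConfig, run_abm
from isbalance.rw import RWConfig, run_simulation


@pytest.fixture(scope="session")
def rw_small_table():
    """Width-dependent run at reduced ensemble size (fast, seeded)."""
    cfg = RWConfig(n0=400, seed=7)
    return run_simulation(cfg)


@pytest.fixture(scope="session")
def abm_colony():
    """One reduced colony with triggered compensation, shared across tests."""
    cfg = ABMConfig(r_final=320.0, ring_radius=90.0, seed=3,
                    mutation_mode="triggered", r_star=130.0)
    table, annotations = run_abm(cfg)
    return cfg, table, annotations
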