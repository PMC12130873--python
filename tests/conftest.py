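"""Shared fixtures: reference parameters, small grids, and cached runs.

Expensive simulations are session-scoped so several tests can share one
solver invocation.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from swarmdrop.grid import Grid1D
from swarmdrop.params import reference_dimensionless
from swarmdrop.simulate import make_initial_condition, run


@pytest.fixture(scope="session")
def ref():
    """Calibrated reference dimensionless parameters."""
    return reference_dimensionless()


@pytest.fixture(scope="session")
def passive(ref):
    """Passive, source-free variant: no activity, no growth, no kinetics."""
    return replace(ref, Ca_xi=0.0, growth=0.0, consumption=0.0, production=0.0)


@pytest.fixture(scope="session")
def small_grid():
    return Grid1D.uniform(0.0, 20.0, 256)


@pytest.fixture(scope="session")
def passive_relaxation(passive, small_grid):
    """A perturbed passive droplet relaxed toward its stationary cap.

    Starts from a deliberately over-stretched profile (S0 ~ 1.6) and runs
    long enough for capillarity and the wetting potential to restore the
    equilibrium cap.  Used by the mass-conservation, energy-dissipation and
    shape-parameter tests.
    """
    ic = make_initial_condition("droplet_on_lawn", small_grid, passive,
                                droplet_volume=1.5, lawn_level=0.0,
                                droplet_center=10.0)
    # compress the cap horizontally at fixed volume: over-steepened slopes
    # relax back by spreading, dissipating interface energy monotonically
    x = small_grid.x
    hs = passive.precursor
    compressed = hs + 1.6 * np.interp((x - 10.0) * 1.6 + 10.0, x, ic.h - hs)
    ic.h = compressed
    return run(ic, small_grid, passive, t_end=30.0, output_interval=1.0)
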