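"""Shared fixtures.

Expensive artifacts (FD solves, calibrations, the eigendecomposition) are
session-scoped so the suite runs each of them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from shuntcable import (
    DEFAULT_PARAMS,
    EigenDecomposition,
    Grid,
    calibrate_strength,
    default_input,
    solve_cable,
    somatic_trace,
)

T_END = 100.0


@pytest.fixture(scope="session")
def params():
    return DEFAULT_PARAMS


@pytest.fixture(scope="session")
def grid(params):
    """Standard production grid: dx = 2 um, dt = 0.05 ms."""
    return Grid.for_cable(params, T_END, dx_um=2.0, dt=0.05)


@pytest.fixture(scope="session")
def coarse_grid(params):
    """Cheap grid for tests that only need qualitative resolution."""
    return Grid.for_cable(params, T_END, dx_um=6.0, dt=0.2)


@pytest.fixture(scope="session")
def decomp(params):
    return EigenDecomposition.compute(params, 80)


@pytest.fixture(scope="session")
def exc_input(params, grid):
    """Excitatory input at 200 um calibrated to a 5 mV somatic EPSP."""
    base = default_input("E", 0.0, 200.0)
    f = calibrate_strength(params, base, 5.0, grid)
    return base.with_strength(f)


@pytest.fixture(scope="session")
def inh_input(params, grid):
    """Inhibitory input at 100 um calibrated to a -2 mV somatic IPSP."""
    base = default_input("I", 0.0, 100.0)
    f = calibrate_strength(params, base, -2.0, grid)
    return base.with_strength(f)


@pytest.fixture(scope="session")
def pair_traces(params, grid, exc_input, inh_input):
    """FD somatic traces for the standard E-I pair: psp1, psp2, ssp."""
    psp1 = somatic_trace(solve_cable(params, [exc_input], grid))
    psp2 = somatic_trace(solve_cable(params, [inh_input], grid))
    ssp = somatic_trace(solve_cable(params, [exc_input, inh_input], grid))
    return psp1, psp2, ssp


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
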