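"""Crank-Nicolson finite-difference solution of the two-compartment cable.

The dendrite [0, L] is discretized into ``nx`` nodes; node 0 is the soma end.
Current conservation on the control volume of each node gives a stiff linear
ODE system

    C dv/dt = -(G + K(t)) v + b(t),

where ``C`` holds the membrane capacitance of each control volume (the soma's
lumped capacitance plus a half dendritic cell at node 0), ``G`` the leak and
axial conductances, ``K(t)`` the synaptic point conductances and ``b(t)`` the
synaptic driving currents f g(t) eps plus any injected current.  The
conductance waveforms are known functions of time, so evaluating them at the
half step keeps each Crank-Nicolson step linear in the unknowns while
retaining second-order accuracy in dt and unconditional stability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.linalg import solve_banded
from scipy.optimize import brentq

from .model import CableParams, StimulusSet, SynapticInput

__all__ = [
    "Grid",
    "VoltageTrace",
    "VoltageField",
    "NumericalFailureError",
    "solve_cable",
    "solve_linear_cable",
    "somatic_trace",
    "calibrate_strength",
]

#: Default discretization: 2 um space step, 0.05 ms time step.
DEFAULT_DX_UM = 2.0
DEFAULT_DT_MS = 0.05


class NumericalFailureError(RuntimeError):
    """Raised when the solver produces non-finite values."""


@dataclass(frozen=True)
class Grid:
    """Uniform space-time grid for the finite-difference solver."""

    dx: float      # cm
    dt: float      # ms
    nx: int
    nt: int        # number of steps; times run 0 .. nt*dt inclusive

    def __post_init__(self) -> None:
        if self.nx < 3:
            raise ValueError("need at least 3 spatial nodes")
        if self.dt <= 0 or self.dx <= 0:
            raise ValueError("dx and dt must be positive")

    @property
    def node_positions(self) -> np.ndarray:
        return np.arange(self.nx) * self.dx

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.nt + 1) * self.dt

    @classmethod
    def for_cable(
        cls,
        params: CableParams,
        t_end: float,
        dx_um: float = DEFAULT_DX_UM,
        dt: float = DEFAULT_DT_MS,
    ) -> "Grid":
        dx = dx_um * 1.0e-4
        nx = int(round(params.length / dx)) + 1
        dx = params.length / (nx - 1)  # snap so dx*(nx-1) == L exactly
        nt = int(round(t_end / dt))
        return cls(dx=dx, dt=dt, nx=nx, nt=nt)

    def check_matches(self, params: CableParams) -> None:
        if abs(self.dx * (self.nx - 1) - params.length) > 1e-9 * params.length:
            raise ValueError("grid does not span the cable length")


@dataclass
class VoltageTrace:
    """A uniformly sampled voltage time series [ms, mV]."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if len(self.times) > 1:
            dts = np.diff(self.times)
            if not np.allclose(dts, dts[0], rtol=1e-8, atol=1e-12):
                raise ValueError("trace must be uniformly sampled")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def _check_compatible(self, other: "VoltageTrace") -> None:
        if self.times.shape != other.times.shape or not np.allclose(
            self.times, other.times, rtol=1e-9, atol=1e-9
        ):
            raise ValueError("traces are on different time bases")

    def __add__(self, other: "VoltageTrace") -> "VoltageTrace":
        self._check_compatible(other)
        return VoltageTrace(self.times, self.values + other.values)

    def __sub__(self, other: "VoltageTrace") -> "VoltageTrace":
        self._check_compatible(other)
        return VoltageTrace(self.times, self.values - other.values)

    def __mul__(self, a: float) -> "VoltageTrace":
        return VoltageTrace(self.times, self.values * float(a))

    __rmul__ = __mul__

    def peak(self) -> tuple[float, float]:
        """(time, value) at the extremum of largest magnitude (earliest on
        ties)."""
        i = int(np.argmax(np.abs(self.values)))
        return float(self.times[i]), float(self.values[i])

    def value_at(self, t: float) -> float:
        return float(np.interp(t, self.times, self.values))


@dataclass
class VoltageField:
    """Space-time membrane potential; values[i, j] at times[i], positions[j].

    The lumped soma and the dendrite origin share node 0, so
    v(0, t) = v_s(t) holds by construction (continuity at the connection
    point).
    """

    times: np.ndarray
    positions: np.ndarray
    values: np.ndarray

    def soma_trace(self) -> VoltageTrace:
        return VoltageTrace(self.times, self.values[:, 0])

    def trace_at(self, x: float) -> VoltageTrace:
        j = int(np.argmin(np.abs(self.positions - x)))
        return VoltageTrace(self.times, self.values[:, j])

    def total_charge(self, params: CableParams) -> np.ndarray:
        """Total membrane charge Q(t) = c_m (integral of pi d v dx + S v_s)
        [nC], using the solver's control volumes."""
        w = _area_weights(params, self.positions)
        return params.c_m * self.values @ w


def _area_weights(params: CableParams, positions: np.ndarray) -> np.ndarray:
    """Membrane area of each node's control volume [cm^2]."""
    dx = positions[1] - positions[0]
    pid = math.pi * params.diameter
    w = np.full(len(positions), pid * dx)
    w[0] = params.soma_area + pid * dx / 2.0
    w[-1] = pid * dx / 2.0
    return w


def _nearest_node(grid: Grid, x: float) -> int:
    return int(round(x / grid.dx))


def _input_node_weights(grid: Grid, x: float, split: bool) -> list[tuple[int, float]]:
    """Distribute a point input onto the grid: nearest node by default,
    linear-interpolation split across the bracketing nodes when requested."""
    if not split:
        return [(_nearest_node(grid, x), 1.0)]
    j = min(int(x / grid.dx), grid.nx - 2)
    frac = x / grid.dx - j
    return [(j, 1.0 - frac), (j + 1, frac)]


def solve_cable(
    params: CableParams,
    stimuli: StimulusSet | Sequence[SynapticInput],
    grid: Grid,
    split_inputs: bool = False,
) -> VoltageField:
    """Solve the full (conductance-nonlinear) cable model from rest.

    Each synaptic input contributes both a diagonal conductance
    pi d f g(t) at its node and a driving current pi d f g(t) eps, so the
    shunting interaction between inputs is fully represented.
    """
    if not isinstance(stimuli, StimulusSet):
        stimuli = StimulusSet(list(stimuli))
    stimuli.validate_locations(params)
    grid.check_matches(params)

    node_inputs: list[tuple[int, float, SynapticInput]] = []
    for inp in stimuli:
        for j, wfrac in _input_node_weights(grid, inp.location, split_inputs):
            node_inputs.append((j, wfrac, inp))

    return _crank_nicolson(
        params, grid,
        conductance_inputs=node_inputs,
        current_density=None,
        point_currents=(),
    )


def solve_linear_cable(
    params: CableParams,
    grid: Grid,
    current_density: Callable[[np.ndarray, float], np.ndarray] | None = None,
    point_currents: Sequence[tuple[float, Callable[[float], float]]] = (),
    initial_impulse: Sequence[tuple[float, float]] = (),
) -> VoltageField:
    """Solve the linearized cable (no conductance-voltage coupling) driven
    by injected currents; the response is exactly linear in the sources.

    Parameters
    ----------
    current_density : callable(positions, t) -> uA/cm^2, optional
        Distributed membrane current (inward positive).
    point_currents : sequence of (location_cm, waveform)
        Point injections; waveform(t) is the delta weight of the current
        density [uA/cm^2 * cm], deposited on the nearest node.
    initial_impulse : sequence of (location_cm, q)
        Instantaneous impulses q delta(x - y) delta(t) applied to the
        per-area equation at t = 0 (the Green's function normalization):
        the charge q pi d lands on the node's capacitance c_m * area.
    """
    grid.check_matches(params)
    pid = math.pi * params.diameter
    v0 = np.zeros(grid.nx)
    if initial_impulse:
        w = _area_weights(params, grid.node_positions)
        for x, q in initial_impulse:
            j = _nearest_node(grid, x)
            v0[j] += q * pid / (params.c_m * w[j])
    return _crank_nicolson(
        params, grid,
        conductance_inputs=[],
        current_density=current_density,
        point_currents=point_currents,
        v_init=v0,
    )


def _crank_nicolson(
    params: CableParams,
    grid: Grid,
    conductance_inputs: list[tuple[int, float, SynapticInput]],
    current_density,
    point_currents,
    v_init: np.ndarray | None = None,
) -> VoltageField:
    nx, nt, dx, dt = grid.nx, grid.nt, grid.dx, grid.dt
    pid = math.pi * params.diameter
    x = grid.node_positions
    w = _area_weights(params, x)
    cap = params.c_m * w                      # uF per node
    g_leak = params.g_L * w                   # mS per node
    g_ax = params.trunk_conductance / dx      # mS between neighbours

    # Static conductance matrix G (tridiagonal, symmetric).
    diag = g_leak.copy()
    diag[0] += g_ax
    diag[-1] += g_ax
    diag[1:-1] += 2.0 * g_ax
    off = np.full(nx - 1, -g_ax)

    point_nodes = [(_nearest_node(grid, xc), f) for xc, f in point_currents]

    v = np.zeros(nx) if v_init is None else np.asarray(v_init, dtype=float).copy()
    out = np.empty((nt + 1, nx))
    out[0] = v

    ab = np.zeros((3, nx))
    ab[0, 1:] = 0.5 * dt * off
    ab[2, :-1] = 0.5 * dt * off

    for n in range(nt):
        t_half = (n + 0.5) * dt
        k_diag = np.zeros(nx)
        b = np.zeros(nx)
        for j, wfrac, inp in conductance_inputs:
            g = pid * inp.strength * wfrac * float(inp.conductance(t_half))
            k_diag[j] += g
            b[j] += g * params.reversal(inp.kind)
        if current_density is not None:
            b += w * np.asarray(current_density(x, t_half), dtype=float)
        for j, f in point_nodes:
            b[j] += pid * float(f(t_half))

        a_diag = diag + k_diag
        ab[1] = cap + 0.5 * dt * a_diag
        rhs = (cap - 0.5 * dt * a_diag) * v
        rhs[:-1] -= 0.5 * dt * off * v[1:]
        rhs[1:] -= 0.5 * dt * off * v[:-1]
        rhs += dt * b
        v = solve_banded((1, 1), ab, rhs)
        out[n + 1] = v

    if not np.all(np.isfinite(out)):
        raise NumericalFailureError("non-finite values in FD solution")
    return VoltageField(times=grid.times, positions=x, values=out)


def somatic_trace(field: VoltageField) -> VoltageTrace:
    """Extract the somatic potential v(0, t)."""
    return field.soma_trace()


def calibrate_strength(
    params: CableParams,
    base_input: SynapticInput,
    target_peak: float,
    grid: Grid,
    tol: float = 1e-4,
) -> float:
    """Bisect on the input strength until the somatic PSP peak magnitude
    equals |target_peak| mV; returns the calibrated strength f."""

    def peak_of(f: float) -> float:
        field = solve_cable(params, [base_input.with_strength(f)], grid)
        _, pv = somatic_trace(field).peak()
        return abs(pv)

    target = abs(target_peak)
    f_probe = 1e-4
    p_probe = peak_of(f_probe)
    if p_probe <= 0:
        raise RuntimeError("probe input produced no response")
    f_lo = f_probe * target / p_probe * 0.5
    f_hi = f_probe * target / p_probe * 1.2
    # conductance responses are sublinear in f, so expand upward as needed
    while peak_of(f_hi) < target:
        f_hi *= 1.5
        if f_hi > 1e3:
            raise RuntimeError("could not bracket the target amplitude")
    while peak_of(f_lo) > target:
        f_lo *= 0.5
    return float(brentq(lambda f: peak_of(f) - target, f_lo, f_hi,
                        rtol=tol, maxiter=80))
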