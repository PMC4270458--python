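"""Physical model of the two-compartment passive neuron.

A spherical, isopotential soma (a lumped RC circuit of membrane area ``S``)
is attached at ``x = 0`` to an unbranched cylindrical dendrite of length
``L`` and diameter ``d``; the far end ``x = L`` is sealed.  The membrane
potential ``v(x, t)`` is measured relative to rest and obeys the passive
cable equation

    c_m dv/dt = (d / (4 r_a)) d^2v/dx^2 - g_L v - I_syn(x, t, v)

with the synaptic current density

    I_syn = g_E(x, t) (v - eps_E) + g_I(x, t) (v - eps_I).

Each synaptic input is a point conductance: a spatial delta of weight ``f``
(the input strength) times a peak-normalized double-exponential waveform in
time.

Internal unit system (dimensionally closed): mV, ms, cm, uF/cm^2, mS/cm^2,
kOhm*cm.  In these units c_m*dv/dt, g_L*v and (d/(4 r_a))*d2v/dx2 are all in
uA/cm^2.  User-facing configuration uses micrometres for lengths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal

import numpy as np

__all__ = [
    "CM_PER_UM",
    "CableParams",
    "SynapticInput",
    "StimulusSet",
    "DegenerateWaveformError",
    "DEFAULT_PARAMS",
    "DEFAULT_KINETICS",
    "unitary_conductance",
    "normalization_factor",
    "conductance_peak_time",
    "synaptic_current_density",
    "default_input",
]

CM_PER_UM = 1.0e-4


class DegenerateWaveformError(ValueError):
    """Raised when sigma_r >= sigma_d, for which the double-exponential
    waveform has no interior maximum."""


@dataclass(frozen=True)
class CableParams:
    """Geometry and passive membrane properties, in internal units.

    Attributes
    ----------
    length : float
        Dendrite length L [cm].
    diameter : float
        Dendrite diameter d [cm].
    soma_area : float
        Somatic membrane area S [cm^2].
    c_m : float
        Membrane capacitance per unit area [uF/cm^2].
    g_L : float
        Leak conductance per unit area [mS/cm^2].
    r_a : float
        Axial resistivity [kOhm*cm].
    eps_E, eps_I : float
        Excitatory / inhibitory reversal potentials relative to rest [mV];
        eps_E > 0, eps_I < 0.
    """

    length: float
    diameter: float
    soma_area: float
    c_m: float
    g_L: float
    r_a: float
    eps_E: float
    eps_I: float

    def __post_init__(self) -> None:
        for name in ("length", "diameter", "soma_area", "c_m", "g_L", "r_a"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not self.eps_E > 0:
            raise ValueError("eps_E must be positive (above rest)")
        if not self.eps_I < 0:
            raise ValueError("eps_I must be negative (below rest)")
        if not math.isfinite(self.tau_m):
            raise ValueError("membrane time constant must be finite")

    @property
    def tau_m(self) -> float:
        """Membrane time constant c_m / g_L [ms]."""
        return self.c_m / self.g_L

    @property
    def axial_coef(self) -> float:
        """Axial diffusion coefficient a = d / (4 r_a) [cm / (kOhm*cm)]."""
        return self.diameter / (4.0 * self.r_a)

    @property
    def trunk_conductance(self) -> float:
        """Axial cross-section factor beta = pi d^2 / (4 r_a) [cm/kOhm];
        beta * dv/dx is the axial current in uA."""
        return math.pi * self.diameter**2 / (4.0 * self.r_a)

    @property
    def soma_length(self) -> float:
        """Electrotonic soma weight gamma = S / (pi d) [cm]: the length of
        dendrite whose membrane area equals the soma's."""
        return self.soma_area / (math.pi * self.diameter)

    def reversal(self, kind: str) -> float:
        return self.eps_E if kind == "E" else self.eps_I

    def digest(self) -> str:
        """Short stable identifier of the physical parameters (ties cached
        eigendecompositions to the cable they describe)."""
        vals = (
            self.length, self.diameter, self.soma_area, self.c_m,
            self.g_L, self.r_a, self.eps_E, self.eps_I,
        )
        return "-".join(f"{v:.12g}" for v in vals)

    @classmethod
    def from_micrometers(
        cls,
        length_um: float,
        diameter_um: float,
        soma_area_um2: float,
        c_m: float,
        g_L: float,
        r_a: float,
        eps_E: float,
        eps_I: float,
    ) -> "CableParams":
        return cls(
            length=length_um * CM_PER_UM,
            diameter=diameter_um * CM_PER_UM,
            soma_area=soma_area_um2 * CM_PER_UM**2,
            c_m=c_m,
            g_L=g_L,
            r_a=r_a,
            eps_E=eps_E,
            eps_I=eps_I,
        )


#: Package-default physiological parameter set: a 600 um x 1 um dendrite on a
#: 25-um spherical soma, tau_m = 20 ms, reversals +70 / -10 mV from rest.
DEFAULT_PARAMS = CableParams.from_micrometers(
    length_um=600.0,
    diameter_um=1.0,
    soma_area_um2=math.pi * 25.0**2,
    c_m=1.0,
    g_L=0.05,
    r_a=0.1,
    eps_E=70.0,
    eps_I=-10.0,
)

#: Default synaptic kinetics (sigma_r, sigma_d) [ms]: slow,
#: iontophoresis-like conductance time courses.
DEFAULT_KINETICS = {"E": (5.0, 7.8), "I": (6.0, 18.0)}


@dataclass(frozen=True)
class SynapticInput:
    """One point synaptic conductance input.

    ``strength`` is the weight f of the spatial delta (conductance density
    times length, mS/cm^2 * cm); ``location`` is the distance from the soma
    [cm]; ``onset`` t0 [ms]; ``sigma_r`` < ``sigma_d`` are the rise and decay
    time constants [ms] of the peak-normalized double exponential.
    """

    kind: Literal["E", "I"]
    strength: float
    location: float
    onset: float = 0.0
    sigma_r: float = 5.0
    sigma_d: float = 7.8
    site_id: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("E", "I"):
            raise ValueError("kind must be 'E' or 'I'")
        if self.strength < 0:
            raise ValueError("strength must be nonnegative")
        if not 0.0 < self.sigma_r < self.sigma_d:
            raise DegenerateWaveformError(
                "require 0 < sigma_r < sigma_d for a double-exponential waveform"
            )

    def conductance(self, t: np.ndarray | float) -> np.ndarray | float:
        """Unit-peak conductance waveform g(t) (dimensionless)."""
        return unitary_conductance(t, self.onset, self.sigma_r, self.sigma_d)

    def with_strength(self, f: float) -> "SynapticInput":
        return replace(self, strength=f)

    def validate_location(self, params: CableParams) -> None:
        if not 0.0 <= self.location <= params.length:
            raise ValueError(
                f"input location {self.location} cm outside cable "
                f"[0, {params.length}]"
            )


@dataclass
class StimulusSet:
    """An ordered collection of synaptic inputs with unique site ids."""

    inputs: list[SynapticInput] = field(default_factory=list)

    def __post_init__(self) -> None:
        labelled = []
        for i, inp in enumerate(self.inputs):
            if inp.site_id is None:
                inp = replace(inp, site_id=f"{inp.kind}{i}")
            labelled.append(inp)
        ids = [inp.site_id for inp in labelled]
        if len(set(ids)) != len(ids):
            raise ValueError("site identifiers must be unique")
        self.inputs = labelled

    def __iter__(self):
        return iter(self.inputs)

    def __len__(self) -> int:
        return len(self.inputs)

    @property
    def n_excitatory(self) -> int:
        return sum(1 for inp in self.inputs if inp.kind == "E")

    @property
    def n_inhibitory(self) -> int:
        return sum(1 for inp in self.inputs if inp.kind == "I")

    def validate_locations(self, params: CableParams) -> None:
        for inp in self.inputs:
            inp.validate_location(params)


def conductance_peak_time(sigma_r: float, sigma_d: float) -> float:
    """Time-to-peak of the raw double exponential (relative to onset).

    Setting d/dt [exp(-t/sigma_d) - exp(-t/sigma_r)] = 0 gives
    t* = sigma_r sigma_d / (sigma_d - sigma_r) * ln(sigma_d / sigma_r).
    """
    if not 0.0 < sigma_r < sigma_d:
        raise DegenerateWaveformError("require 0 < sigma_r < sigma_d")
    return sigma_r * sigma_d / (sigma_d - sigma_r) * math.log(sigma_d / sigma_r)


def normalization_factor(sigma_r: float, sigma_d: float) -> float:
    """Factor N with N * (exp(-t*/sigma_d) - exp(-t*/sigma_r)) = 1 at the
    peak time t*; always > 1 since the raw peak is below one."""
    t_star = conductance_peak_time(sigma_r, sigma_d)
    return 1.0 / (math.exp(-t_star / sigma_d) - math.exp(-t_star / sigma_r))


def unitary_conductance(
    t: np.ndarray | float, t0: float, sigma_r: float, sigma_d: float
) -> np.ndarray | float:
    """Peak-normalized double-exponential conductance waveform.

    g(t) = N [exp(-(t - t0)/sigma_d) - exp(-(t - t0)/sigma_r)] H(t - t0),
    with N chosen so max_t g(t) = 1.  Returns 0 for t <= t0.
    """
    n = normalization_factor(sigma_r, sigma_d)
    tt = np.asarray(t, dtype=float) - t0
    pos = np.clip(tt, 0.0, None)
    out = np.where(tt > 0.0, n * (np.exp(-pos / sigma_d) - np.exp(-pos / sigma_r)), 0.0)
    if np.isscalar(t) or np.ndim(t) == 0:
        return float(out)
    return out


def synaptic_current_density(
    v_local: float,
    active_inputs: Iterable[SynapticInput],
    t: float,
    params: CableParams,
) -> float:
    """Delta-weighted synaptic current density at one site [uA/cm^2 * cm].

    Sum over inputs of f * g(t) * (v_local - eps); positive values are
    outward (hyperpolarizing).  Zero when no input is active.
    """
    total = 0.0
    for inp in active_inputs:
        total += inp.strength * float(inp.conductance(t)) * (
            v_local - params.reversal(inp.kind)
        )
    return total


def default_input(
    kind: str,
    strength: float,
    location_um: float,
    onset: float = 0.0,
    site_id: str | None = None,
) -> SynapticInput:
    """Convenience constructor using default kinetics and um locations."""
    sr, sd = DEFAULT_KINETICS[kind]
    return SynapticInput(
        kind=kind,  # type: ignore[arg-type]
        strength=strength,
        location=location_um * CM_PER_UM,
        onset=onset,
        sigma_r=sr,
        sigma_d=sd,
        site_id=site_id,
    )
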