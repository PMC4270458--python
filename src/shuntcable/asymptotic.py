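"""Perturbative solution of the cable model in powers of input strengths.

For a pair of inputs with strengths f_a, f_b the membrane potential is
expanded as v = sum_{j,k} f_a^j f_b^k v^{(j,k)}.  Collecting powers gives a
hierarchy of linear cable equations, each driven by a source localized at
an input site and solved by convolving the Green's function in time:

  order 0:       v^(0) = 0 (resting state);
  order f:       source  +delta(x - y) g(t) eps          (driving force at
                 rest), giving the first-order PSP;
  order f^2:     source  -delta(x - y) g(t) v^(1)(y, t)  (the conductance
                 times the first-order local potential), an opposite-sign
                 self-correction — sublinearity of a single input;
  order f_a f_b: sources -delta(x - y_a) g_a(t) v_b^(1)(y_a, t)
                         -delta(x - y_b) g_b(t) v_a^(1)(y_b, t),
                 the cross term whose somatic trace is the shunting
                 component per unit f_a f_b.

Because every conductance is a spatial delta, the spatial integrals
collapse to evaluations at the input sites, and each component is stored as
per-mode convolution integrals (see ``green.ModalResponse``).

All components here are per unit strength: multiply by f, f^2 or f_a f_b
when composing PSPs (``compose_psp``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fd import VoltageTrace
from .green import EigenDecomposition, ModalResponse, mode_convolution
from .model import CableParams, SynapticInput

__all__ = [
    "AsymptoticSolution",
    "first_order_response",
    "second_order_self",
    "cross_term",
    "simplified_cross_term",
    "compose_psp",
]


def _check(params: CableParams, decomp: EigenDecomposition,
           *inputs: SynapticInput) -> None:
    decomp.check_params(params)
    for inp in inputs:
        inp.validate_location(params)


def first_order_response(
    params: CableParams,
    inp: SynapticInput,
    decomp: EigenDecomposition,
    times: np.ndarray,
) -> ModalResponse:
    """First-order field per unit strength: G(x, y, .) convolved with the
    resting-state synaptic current g(t) eps.  Zero before onset; linear in
    the reversal potential."""
    _check(params, decomp, inp)
    q = params.reversal(inp.kind) * np.asarray(inp.conductance(times), dtype=float)
    c = mode_convolution(decomp.poles, q, float(times[1] - times[0]))
    return ModalResponse(params, decomp, times, [(inp.location, c)])


def second_order_self(
    params: CableParams,
    inp: SynapticInput,
    v1: ModalResponse,
    decomp: EigenDecomposition,
) -> ModalResponse:
    """Second-order self-correction per unit strength squared.

    The source is minus the local conductance times the first-order local
    potential at the input site; for an excitatory input the somatic
    correction opposes the first-order EPSP (sublinear summation).
    """
    _check(params, decomp, inp)
    times = v1.times
    local = v1.at(inp.location).values
    q = -np.asarray(inp.conductance(times), dtype=float) * local
    c = mode_convolution(decomp.poles, q, float(times[1] - times[0]))
    return ModalResponse(params, decomp, times, [(inp.location, c)])


def cross_term(
    params: CableParams,
    inp_a: SynapticInput,
    inp_b: SynapticInput,
    v1_a: ModalResponse,
    v1_b: ModalResponse,
    decomp: EigenDecomposition,
) -> ModalResponse:
    """Cross component v^(1,1) per unit f_a f_b, for any pair of kinds.

    Symmetric under relabelling the pair; identically zero if either input's
    conductance never overlaps the other's first-order response (e.g. for
    onset separations much longer than the membrane time constant).
    """
    _check(params, decomp, inp_a, inp_b)
    times = v1_a.times
    dt = float(times[1] - times[0])
    q_at_a = -np.asarray(inp_a.conductance(times), dtype=float) * v1_b.at(
        inp_a.location
    ).values
    q_at_b = -np.asarray(inp_b.conductance(times), dtype=float) * v1_a.at(
        inp_b.location
    ).values
    contributions = [
        (inp_a.location, mode_convolution(decomp.poles, q_at_a, dt)),
        (inp_b.location, mode_convolution(decomp.poles, q_at_b, dt)),
    ]
    return ModalResponse(params, decomp, times, contributions)


def simplified_cross_term(
    params: CableParams,
    inp_e: SynapticInput,
    inp_i: SynapticInput,
    v1_e: ModalResponse,
    decomp: EigenDecomposition,
) -> ModalResponse:
    """Reduced E-I cross term keeping only the outward current induced by
    the first-order EPSP at the inhibitory site.

    Valid because the excitatory reversal potential is nearly an order of
    magnitude farther from rest than the inhibitory one, so the g_E * v_I^1
    source is comparatively negligible.
    """
    _check(params, decomp, inp_e, inp_i)
    times = v1_e.times
    dt = float(times[1] - times[0])
    q = -np.asarray(inp_i.conductance(times), dtype=float) * v1_e.at(
        inp_i.location
    ).values
    return ModalResponse(
        params, decomp, times, [(inp_i.location, mode_convolution(decomp.poles, q, dt))]
    )


@dataclass
class AsymptoticSolution:
    """Order-indexed components (per unit strength) for up to two inputs.

    ``v1_a``/``v2_a`` belong to input ``a``, ``v1_b``/``v2_b`` to input
    ``b``; ``v11`` is the cross component.  Strengths are carried
    separately so rescaling an input only rescales the composition.
    """

    input_a: SynapticInput
    input_b: SynapticInput | None
    v1_a: ModalResponse
    v2_a: ModalResponse
    v1_b: ModalResponse | None = None
    v2_b: ModalResponse | None = None
    v11: ModalResponse | None = None

    @classmethod
    def build(
        cls,
        params: CableParams,
        decomp: EigenDecomposition,
        times: np.ndarray,
        input_a: SynapticInput,
        input_b: SynapticInput | None = None,
    ) -> "AsymptoticSolution":
        v1_a = first_order_response(params, input_a, decomp, times)
        v2_a = second_order_self(params, input_a, v1_a, decomp)
        if input_b is None:
            return cls(input_a, None, v1_a, v2_a)
        v1_b = first_order_response(params, input_b, decomp, times)
        v2_b = second_order_self(params, input_b, v1_b, decomp)
        v11 = cross_term(params, input_a, input_b, v1_a, v1_b, decomp)
        return cls(input_a, input_b, v1_a, v2_a, v1_b, v2_b, v11)

    def psp_a(self) -> VoltageTrace:
        f = self.input_a.strength
        return f * self.v1_a.soma() + f * f * self.v2_a.soma()

    def psp_b(self) -> VoltageTrace:
        if self.input_b is None:
            raise ValueError("solution has no second input")
        f = self.input_b.strength
        return f * self.v1_b.soma() + f * f * self.v2_b.soma()

    def ssp(self) -> VoltageTrace:
        if self.input_b is None:
            return self.psp_a()
        fab = self.input_a.strength * self.input_b.strength
        return self.psp_a() + self.psp_b() + fab * self.v11.soma()


def compose_psp(kind: str, solution: AsymptoticSolution) -> VoltageTrace:
    """Somatic second-order composition.

    kind='EPSP' or 'IPSP' reads the matching single input (f v1 + f^2 v2);
    kind='SSP' adds both PSPs and the bilinear cross term f_a f_b v11.
    With a zero-strength or absent second input the SSP reduces to the
    single PSP.
    """
    if kind == "SSP":
        return solution.ssp()
    if kind in ("EPSP", "IPSP"):
        want = "E" if kind == "EPSP" else "I"
        if solution.input_a.kind == want:
            return solution.psp_a()
        if solution.input_b is not None and solution.input_b.kind == want:
            return solution.psp_b()
        raise ValueError(f"solution has no {want} input")
    raise ValueError("kind must be 'EPSP', 'IPSP' or 'SSP'")
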