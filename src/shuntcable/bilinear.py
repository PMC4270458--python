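"""Shunting component, shunting coefficient, bilinear rules and the
dendritic interaction graph.

The shunting component (SC) is the deviation of the summed somatic
potential from the linear sum of the individually elicited PSPs,

    SC(t) = SSP(t) - PSP_1(t) - PSP_2(t),

and, to leading order in the input strengths, SC = f_1 f_2 v^(1,1)(0, t).
The shunting coefficient

    k(t) = v^(1,1)(0, t) / (v_1^(1)(0, t) v_2^(1)(0, t))

is independent of the strengths by construction (they cancel in numerator
and denominator), giving the bilinear integration rule

    SSP ~= PSP_1 + PSP_2 + k PSP_1 PSP_2,

valid for E-I, E-E and I-I pairs, and for many inputs as the sum of all
PSPs plus all pairwise bilinear interactions.  Mapping sites to nodes and
pairwise SC amplitudes to edge weights yields a time-evolving "dendritic
graph" that is all-to-all for concurrent stimuli but functionally sparse
for realistic asynchronous input.

``k`` is stored signed: for E-I pairs SC < 0 and the IPSP < 0, so k > 0;
for E-E pairs SC < 0 and both PSPs > 0, so k < 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .asymptotic import cross_term, first_order_response
from .fd import VoltageTrace
from .green import EigenDecomposition
from .model import CableParams, StimulusSet, SynapticInput

__all__ = [
    "ShuntingCoefficient",
    "DendriticGraph",
    "WindowViolationError",
    "shunting_component",
    "shunting_coefficient_analytic",
    "predict_pair",
    "predict_multi",
    "spatial_k_profile",
    "build_graph",
    "active_edges",
    "expected_active_pairs",
]

#: Fraction of each PSP's peak below which k is not evaluated (the SC is
#: negligible there and the quotient denominator would be small).
DEFAULT_WINDOW_FRACTION = 0.1


class WindowViolationError(ValueError):
    """Raised when the denominator underflows inside a requested window."""


@dataclass
class ShuntingCoefficient:
    """Time course of k [1/mV] with its validity window.

    ``values`` holds k(t) where ``valid`` is True and 0 elsewhere; outside
    the window the bilinear correction is negligible and prediction falls
    back to the linear sum.  ``meta`` records the pair (site ids, kinds,
    locations, onset difference) and ``provenance`` is 'analytic' or
    'regression'; regression estimates may attach per-time CI and R^2.
    """

    times: np.ndarray
    values: np.ndarray
    valid: np.ndarray
    provenance: str = "analytic"
    meta: dict = field(default_factory=dict)
    ci_lo: np.ndarray | None = None
    ci_hi: np.ndarray | None = None
    r2: np.ndarray | None = None

    def at(self, t: float) -> float:
        i = int(np.argmin(np.abs(self.times - t)))
        return float(self.values[i])

    def valid_at(self, t: float) -> bool:
        i = int(np.argmin(np.abs(self.times - t)))
        return bool(self.valid[i])

    def extended(self) -> np.ndarray:
        """k(t) continued outside the validity window by its nearest valid
        value.  The window floor protects the *estimation* of k from small
        denominators; the coefficient itself varies smoothly, so holding
        the edge value is the right continuation when *applying* k (the
        correction k PSP1 PSP2 vanishes with the PSPs anyway).  All-invalid
        coefficients extend to zero."""
        idx = np.flatnonzero(self.valid)
        if idx.size == 0:
            return np.zeros_like(self.values)
        return np.interp(
            np.arange(len(self.values)), idx, self.values[idx]
        )


def shunting_component(
    ssp: VoltageTrace, psp1: VoltageTrace, psp2: VoltageTrace
) -> VoltageTrace:
    """SC(t) = SSP(t) - PSP1(t) - PSP2(t), pointwise on a shared time base."""
    return ssp - psp1 - psp2


def _window_mask(
    times: np.ndarray,
    v1a: VoltageTrace,
    v1b: VoltageTrace,
    window: tuple[float, float] | None,
    rel_floor: float,
) -> np.ndarray:
    amp_a = np.abs(v1a.values)
    amp_b = np.abs(v1b.values)
    mask = (amp_a >= rel_floor * amp_a.max()) & (amp_b >= rel_floor * amp_b.max())
    if window is not None:
        in_win = (times >= window[0]) & (times <= window[1])
        if np.any(in_win & ~mask):
            raise WindowViolationError(
                "denominator below the validity floor inside the requested window"
            )
        mask = in_win
    return mask


def shunting_coefficient_analytic(
    v11: VoltageTrace,
    v1a: VoltageTrace,
    v1b: VoltageTrace,
    window: tuple[float, float] | None = None,
    rel_floor: float = DEFAULT_WINDOW_FRACTION,
    meta: dict | None = None,
) -> ShuntingCoefficient:
    """k(t) = v11(t) / (v1a(t) v1b(t)) inside the validity window.

    The inputs are the per-unit-strength somatic components, so k is exactly
    invariant under rescaling either input strength.  Outside the window
    (either factor below ``rel_floor`` of its peak) k is reported as 0 and
    flagged invalid.
    """
    v1a._check_compatible(v1b)
    v1a._check_compatible(v11)
    times = v1a.times
    mask = _window_mask(times, v1a, v1b, window, rel_floor)
    denom = v1a.values * v1b.values
    k = np.zeros_like(denom)
    k[mask] = v11.values[mask] / denom[mask]
    return ShuntingCoefficient(
        times=times, values=k, valid=mask, provenance="analytic",
        meta=meta or {},
    )


def predict_pair(
    psp1: VoltageTrace, psp2: VoltageTrace, k: ShuntingCoefficient
) -> VoltageTrace:
    """Bilinear prediction PSP1 + PSP2 + k PSP1 PSP2, symmetric under
    swapping the pair.  Outside k's validity window the coefficient is
    continued by its nearest valid value (see
    :meth:`ShuntingCoefficient.extended`)."""
    psp1._check_compatible(psp2)
    if psp1.times.shape != k.times.shape or not np.allclose(psp1.times, k.times):
        raise ValueError("coefficient and traces are on different time bases")
    corr = k.extended() * psp1.values * psp2.values
    return VoltageTrace(psp1.times, psp1.values + psp2.values + corr)


def predict_multi(
    psps: dict[str, VoltageTrace],
    k_table: dict[frozenset, ShuntingCoefficient],
) -> VoltageTrace:
    """Multi-input bilinear rule: sum of all PSPs plus all pairwise
    bilinear interactions.  Pairs missing from ``k_table`` are treated as
    non-interacting (k = 0) with a warning."""
    ids = list(psps)
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate site ids")
    base = next(iter(psps.values()))
    total = np.zeros_like(base.values)
    for tr in psps.values():
        base._check_compatible(tr)
        total = total + tr.values
    for i, id_a in enumerate(ids):
        for id_b in ids[i + 1:]:
            key = frozenset((id_a, id_b))
            k = k_table.get(key)
            if k is None:
                warnings.warn(f"no shunting coefficient for pair {set(key)}; "
                              "assuming linear summation")
                continue
            total = total + k.extended() * psps[id_a].values * psps[id_b].values
    return VoltageTrace(base.times, total)


def spatial_k_profile(
    params: CableParams,
    x_inh: float,
    x_exc_list: list[float],
    decomp: EigenDecomposition,
    times: np.ndarray,
    exc_template: SynapticInput | None = None,
    inh_template: SynapticInput | None = None,
) -> np.ndarray:
    """k at the EPSP-peak time for concurrent E-I pairs with the inhibitory
    site fixed and the excitatory site varied.

    On the unbranched cable k is nondecreasing in the excitatory distance
    from the soma for sites between the soma and the inhibitory site.
    """
    from .model import default_input

    if inh_template is None:
        inh_template = default_input("I", 1.0, 0.0)
    inh = SynapticInput(
        kind="I", strength=1.0, location=x_inh, onset=inh_template.onset,
        sigma_r=inh_template.sigma_r, sigma_d=inh_template.sigma_d,
    )
    v1_i = first_order_response(params, inh, decomp, times)
    out = []
    for x_e in x_exc_list:
        if exc_template is None:
            exc_template = default_input("E", 1.0, 0.0)
        exc = SynapticInput(
            kind="E", strength=1.0, location=x_e, onset=exc_template.onset,
            sigma_r=exc_template.sigma_r, sigma_d=exc_template.sigma_d,
        )
        v1_e = first_order_response(params, exc, decomp, times)
        v11 = cross_term(params, exc, inh, v1_e, v1_i, decomp)
        k = shunting_coefficient_analytic(
            v11.soma(), v1_e.soma(), v1_i.soma(),
            meta={"x_E": x_e, "x_I": x_inh},
        )
        t_peak, _ = v1_e.soma().peak()
        out.append(k.at(t_peak))
    return np.asarray(out)


@dataclass
class DendriticGraph:
    """Nodes are input sites; edges carry pairwise SC-weight time series."""

    graph: nx.Graph
    times: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_graph(
    stimuli: StimulusSet,
    sc_table: dict[frozenset, VoltageTrace],
) -> DendriticGraph:
    """Assemble the dendritic graph from a stimulus set and pairwise SC
    traces (edge weight series)."""
    g = nx.Graph()
    for inp in stimuli:
        g.add_node(inp.site_id, kind=inp.kind, location=inp.location,
                   onset=inp.onset)
    times = None
    for key, sc in sc_table.items():
        a, b = sorted(key)
        if a == b:
            raise ValueError("edges must connect distinct sites")
        g.add_edge(a, b, weight_series=sc.values)
        times = sc.times
    if times is None:
        times = np.zeros(0)
    return DendriticGraph(graph=g, times=times)


def active_edges(
    graph: DendriticGraph, t: float, threshold: float
) -> tuple[list[tuple[str, str]], float]:
    """Edges with |SC(t)| >= threshold [mV], and their fraction of the
    all-to-all pair count C(n, 2).  Nonincreasing in the threshold."""
    if len(graph.times) and not (graph.times[0] <= t <= graph.times[-1]):
        raise ValueError("t outside the simulated interval")
    i = int(np.argmin(np.abs(graph.times - t))) if len(graph.times) else 0
    active = [
        (a, b)
        for a, b, data in graph.graph.edges(data=True)
        if abs(data["weight_series"][i]) >= threshold
    ]
    n = graph.n_nodes
    total = n * (n - 1) / 2
    return active, (len(active) / total if total else 0.0)


def expected_active_pairs(
    n_synapses: float, rate: float, window: float
) -> tuple[float, float]:
    """Expected concurrently-active pair count within a coincidence window.

    With ``n_synapses`` afferents firing at ``rate`` [events/s], the mean
    number of inputs inside a window of ``window`` seconds is
    m = n_synapses * rate * window; the expected interacting pairs are
    m (m - 1) / 2, reported with their fraction of all C(n_synapses, 2)
    possible pairs — far below 1 in cortical conditions, which is the
    functional-sparsity estimate for the dendritic graph.
    """
    if n_synapses < 0 or rate < 0 or window < 0:
        raise ValueError("arguments must be nonnegative")
    m = n_synapses * rate * window
    pairs = max(m * (m - 1) / 2.0, 0.0)
    total = n_synapses * (n_synapses - 1) / 2.0
    return pairs, (pairs / total if total > 0 else 0.0)


def graph_to_node_link(graph: DendriticGraph, at_time: float | None = None) -> dict:
    """JSON-serializable node-link dict; edge weights are scalars at
    ``at_time`` (defaults to each edge's peak |SC|)."""
    g = nx.Graph()
    g.add_nodes_from(graph.graph.nodes(data=True))
    for a, b, data in graph.graph.edges(data=True):
        series = data["weight_series"]
        if at_time is None:
            wval = float(np.max(np.abs(series))) if len(series) else 0.0
        else:
            i = int(np.argmin(np.abs(graph.times - at_time)))
            wval = float(series[i])
        g.add_edge(a, b, weight=wval)
    return nx.node_link_data(g, edges="links")
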