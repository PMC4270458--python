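"""Shunting component/coefficient, bilinear prediction, dendritic graph."""

import numpy as np
import pytest

from shuntcable import (
    StimulusSet,
    VoltageTrace,
    active_edges,
    build_graph,
    cross_term,
    expected_active_pairs,
    first_order_response,
    predict_multi,
    predict_pair,
    shunting_coefficient_analytic,
    shunting_component,
    solve_cable,
    somatic_trace,
    spatial_k_profile,
)
from shuntcable.bilinear import WindowViolationError, graph_to_node_link
from shuntcable.model import default_input


@pytest.fixture(scope="module")
def analytic_k(params, decomp, grid, exc_input, inh_input):
    times = grid.times
    v1e = first_order_response(params, exc_input, decomp, times)
    v1i = first_order_response(params, inh_input, decomp, times)
    v11 = cross_term(params, exc_input, inh_input, v1e, v1i, decomp)
    return v1e, v1i, v11, shunting_coefficient_analytic(
        v11.soma(), v1e.soma(), v1i.soma()
    )


class TestShuntingComponent:
    def test_identity(self, pair_traces):
        psp1, psp2, ssp = pair_traces
        sc = shunting_component(ssp, psp1, psp2)
        assert np.allclose(sc.values, ssp.values - psp1.values - psp2.values,
                           atol=0)

    def test_ei_sublinear_at_epsp_peak(self, pair_traces):
        """Sub-linearity (E-I): SC <= 0 at the EPSP peak."""
        psp1, psp2, ssp = pair_traces
        sc = shunting_component(ssp, psp1, psp2)
        i = int(np.argmax(psp1.values))
        assert sc.values[i] < 0.0

    def test_ee_sublinear_and_small(self, params, grid):
        """Sub-linearity (E-E): SC < 0 and |SC|/SSP < 0.05 at equal
        3 mV EPSPs (mid-physiological amplitude)."""
        from shuntcable import calibrate_strength

        a = default_input("E", 0.0, 200.0)
        b = default_input("E", 0.0, 350.0)
        fa = calibrate_strength(params, a, 3.0, grid)
        fb = calibrate_strength(params, b, 3.0, grid)
        p1 = somatic_trace(solve_cable(params, [a.with_strength(fa)], grid))
        p2 = somatic_trace(solve_cable(params, [b.with_strength(fb)], grid))
        ssp = somatic_trace(
            solve_cable(params, [a.with_strength(fa), b.with_strength(fb)], grid)
        )
        sc = shunting_component(ssp, p1, p2)
        i = int(np.argmax(p1.values))
        assert sc.values[i] < 0.0
        assert abs(sc.values[i]) / ssp.values[i] < 0.05


class TestShuntingCoefficient:
    def test_strength_invariance_exact(self, analytic_k):
        # the analytic quotient is built per unit strength: rescaling the
        # numerator by f_a f_b and each denominator factor cancels exactly
        v1e, v1i, v11, k = analytic_k
        k2 = shunting_coefficient_analytic(
            3.0 * v11.soma(), 1.5 * v1e.soma(), 2.0 * v1i.soma()
        )
        assert np.allclose(k2.values, k.values, rtol=1e-12)
        assert np.array_equal(k2.valid, k.valid)

    def test_ei_coefficient_positive(self, analytic_k):
        # E-I: SC < 0 and the IPSP factor < 0, so k > 0 in the window
        _, _, _, k = analytic_k
        assert np.all(k.values[k.valid] > 0.0)

    def test_invalid_region_reported_zero(self, analytic_k):
        _, _, _, k = analytic_k
        assert np.all(k.values[~k.valid] == 0.0)
        # early times are always outside the window (both PSPs near zero)
        assert not k.valid[0]

    def test_window_violation_raises(self, analytic_k):
        v1e, v1i, v11, _ = analytic_k
        with pytest.raises(WindowViolationError):
            shunting_coefficient_analytic(
                v11.soma(), v1e.soma(), v1i.soma(), window=(0.0, 100.0)
            )

    def test_explicit_window_inside_valid_region(self, analytic_k):
        v1e, v1i, v11, k = analytic_k
        t_ok = k.times[k.valid]
        win = (float(t_ok[5]), float(t_ok[-5]))
        k2 = shunting_coefficient_analytic(
            v11.soma(), v1e.soma(), v1i.soma(), window=win
        )
        inside = (k.times >= win[0]) & (k.times <= win[1])
        assert np.array_equal(k2.valid, inside)

    def test_extended_fills_edges(self, analytic_k):
        _, _, _, k = analytic_k
        ext = k.extended()
        idx = np.flatnonzero(k.valid)
        assert np.allclose(ext[idx], k.values[idx], atol=0)
        assert np.all(ext[: idx[0]] == k.values[idx[0]])
        assert np.all(ext[idx[-1]:] == k.values[idx[-1]])

    def test_extended_all_invalid_is_zero(self):
        t = np.arange(5.0)
        from shuntcable.bilinear import ShuntingCoefficient

        k = ShuntingCoefficient(t, np.zeros(5), np.zeros(5, dtype=bool))
        assert np.all(k.extended() == 0.0)

    def test_matches_fd_derived_k(self, params, grid, exc_input, inh_input,
                                  pair_traces, analytic_k):
        # k from FD traces at the EPSP peak approximates the analytic k
        psp1, psp2, ssp = pair_traces
        _, _, _, k = analytic_k
        i = int(np.argmax(psp1.values))
        k_fd = (ssp.values[i] - psp1.values[i] - psp2.values[i]) / (
            psp1.values[i] * psp2.values[i]
        )
        assert k_fd == pytest.approx(k.values[i], rel=0.05)


class TestPrediction:
    def test_pair_prediction_accuracy(self, pair_traces, analytic_k):
        """Bilinear rule at physiological strengths: error < 3% of the SSP
        peak over the whole trace."""
        psp1, psp2, ssp = pair_traces
        _, _, _, k = analytic_k
        pred = predict_pair(psp1, psp2, k)
        scale = np.max(np.abs(ssp.values))
        assert np.max(np.abs(pred.values - ssp.values)) / scale < 0.03

    def test_pair_prediction_symmetric(self, pair_traces, analytic_k):
        psp1, psp2, _ = pair_traces
        _, _, _, k = analytic_k
        ab = predict_pair(psp1, psp2, k)
        ba = predict_pair(psp2, psp1, k)
        assert np.allclose(ab.values, ba.values, atol=0)

    def test_pair_beats_linear_sum(self, pair_traces, analytic_k):
        psp1, psp2, ssp = pair_traces
        _, _, _, k = analytic_k
        pred = predict_pair(psp1, psp2, k)
        lin = psp1 + psp2
        assert np.max(np.abs(pred.values - ssp.values)) < 0.5 * np.max(
            np.abs(lin.values - ssp.values)
        )

    def test_time_base_mismatch_rejected(self, pair_traces, analytic_k):
        psp1, psp2, _ = pair_traces
        _, _, _, k = analytic_k
        short = VoltageTrace(psp1.times[:-1], psp1.values[:-1])
        with pytest.raises(ValueError):
            predict_pair(short, VoltageTrace(psp2.times[:-1], psp2.values[:-1]),
                         k)

    def test_multi_reduces_to_pair(self, pair_traces, analytic_k, exc_input,
                                   inh_input):
        psp1, psp2, _ = pair_traces
        _, _, _, k = analytic_k
        pair_pred = predict_pair(psp1, psp2, k)
        multi_pred = predict_multi(
            {"e": psp1, "i": psp2},
            {frozenset(("e", "i")): k},
        )
        assert np.allclose(multi_pred.values, pair_pred.values, atol=0)

    def test_multi_missing_pair_warns(self, pair_traces):
        psp1, psp2, _ = pair_traces
        with pytest.warns(UserWarning):
            out = predict_multi({"e": psp1, "i": psp2}, {})
        assert np.allclose(out.values, (psp1 + psp2).values, atol=0)


class TestSpatialProfile:
    def test_k_monotone_toward_inhibitory_site(self, params, decomp, grid):
        """For E sites between the soma and the fixed I site, k grows with
        the excitatory site's distance from the soma."""
        x_i = 300.0e-4
        xs = [50.0e-4, 120.0e-4, 200.0e-4, 280.0e-4]
        ks = spatial_k_profile(params, x_i, xs, decomp, grid.times)
        assert np.all(np.diff(ks) > 0.0)
        assert np.all(ks > 0.0)


class TestGraph:
    def _toy_graph(self, n=4):
        times = np.arange(0.0, 10.0, 1.0)
        inputs = [default_input("E", 0.01, 100.0 + 50.0 * j, site_id=f"s{j}")
                  for j in range(n)]
        stim = StimulusSet(inputs)
        sc_table = {}
        for a in range(n):
            for b in range(a + 1, n):
                mag = 0.1 * (a + b + 1)
                sc_table[frozenset((f"s{a}", f"s{b}"))] = VoltageTrace(
                    times, -mag * np.ones_like(times)
                )
        return build_graph(stim, sc_table), times

    def test_counts(self):
        g, _ = self._toy_graph(4)
        assert g.n_nodes == 4
        assert g.n_edges == 6

    def test_active_edges_monotone_in_threshold(self):
        g, times = self._toy_graph(4)
        t = float(times[3])
        counts = [len(active_edges(g, t, thr)[0]) for thr in (0.0, 0.25, 0.45, 9.9)]
        assert counts == sorted(counts, reverse=True)
        assert counts[0] == 6 and counts[-1] == 0

    def test_active_fraction(self):
        g, times = self._toy_graph(4)
        _, frac = active_edges(g, float(times[0]), 0.45)
        assert 0.0 <= frac <= 1.0

    def test_time_outside_interval_rejected(self):
        g, _ = self._toy_graph(3)
        with pytest.raises(ValueError):
            active_edges(g, 99.0, 0.0)

    def test_node_link_serializable(self):
        import json

        g, times = self._toy_graph(3)
        doc = graph_to_node_link(g)
        json.dumps(doc)
        assert len(doc["nodes"]) == 3
        assert len(doc["links"]) == 3

    def test_expected_active_pairs_sparse(self):
        # thousands of synapses at cortical rates in a tau_m-scale window:
        # functionally sparse (fraction << 1)
        pairs, frac = expected_active_pairs(1000, 1.0, 0.02)
        assert pairs == pytest.approx(20 * 19 / 2.0)
        assert frac < 0.001

    def test_expected_active_pairs_trivials(self):
        assert expected_active_pairs(0, 1.0, 1.0) == (0.0, 0.0)
        pairs, _ = expected_active_pairs(10, 0.0, 1.0)
        assert pairs == 0.0
        with pytest.raises(ValueError):
            expected_active_pairs(-1, 1.0, 1.0)
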