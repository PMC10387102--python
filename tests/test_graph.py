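import numpy as np
import pytest

from mfnet.correlation import CorrelationResult, PairCorrelation, bin_trains, pair_correlation
from mfnet.detection import SpikeTrainSet
from mfnet.geometry import EdgeClass
from mfnet.graph import (
    ConnectivityEdge,
    classify_edges,
    delayed_graph,
    node_roles,
    short_term_graph,
    to_networkx,
)


def pc(a, b, lag, p, cmax=0.8):
    return PairCorrelation(
        a=a, b=b, c0=cmax if lag == 0 else 0.1, c_max=cmax,
        lag_bins=lag, delay_ms=lag * 5.0, p_value=p,
    )


@pytest.fixture
def cc_result():
    pairs = {
        ("14", "34"): pc("14", "34", +2, 0.001),   # delayed, 14 leads
        ("34", "44"): pc("34", "44", 0, 0.001),    # short-term
        ("44", "64"): pc("44", "64", -1, 0.001),   # delayed, 64 leads
        ("34", "64"): pc("34", "64", +1, 0.5),     # not significant
        ("37", "47"): pc("37", "47", 0, 0.5),      # not significant
    }
    return CorrelationResult(pairs=pairs, bin_ms=5.0, max_lag_bins=5)


class TestWindows:
    def test_short_term_keeps_central_bin_maxima_only(self, cc_result, layout):
        edges = short_term_graph(cc_result, layout, alpha=0.01)
        assert {(e.from_electrode, e.to_electrode) for e in edges} == {("34", "44")}
        assert edges[0].delay_ms == 0.0
        assert edges[0].edge_class is EdgeClass.SAME_LINE

    def test_delayed_oriented_by_delay_sign(self, cc_result, layout):
        edges = delayed_graph(cc_result, layout, alpha=0.01)
        got = {(e.from_electrode, e.to_electrode): e.delay_ms for e in edges}
        assert got == {("14", "34"): 10.0, ("64", "44"): 5.0}

    def test_window_partition_disjoint(self, cc_result, layout):
        short = {(e.from_electrode, e.to_electrode) for e in short_term_graph(cc_result, layout, 0.01)}
        delayed = {
            tuple(sorted((e.from_electrode, e.to_electrode)))
            for e in delayed_graph(cc_result, layout, 0.01)
        }
        assert not short & delayed

    def test_insignificant_pairs_excluded_everywhere(self, cc_result, layout):
        all_edges = short_term_graph(cc_result, layout, 0.01) + delayed_graph(cc_result, layout, 0.01)
        touched = {frozenset((e.from_electrode, e.to_electrode)) for e in all_edges}
        assert frozenset(("34", "64")) not in touched
        assert frozenset(("37", "47")) not in touched

    def test_orientation_flips_under_time_reversal(self):
        """Reversing all spike times must reverse every delayed edge."""
        rng = np.random.default_rng(0)
        t_a = np.sort(rng.uniform(0, 20, 120))
        t_b = np.sort(t_a + 0.010)
        duration = 20.5

        def delayed_lag(x_times, y_times):
            trains = SpikeTrainSet(trains={"a": x_times, "b": y_times}, duration=duration)
            b = bin_trains(trains)
            return pair_correlation(b.vector("a"), b.vector("b"), 5.0, 5).lag_bins

        fwd = delayed_lag(t_a, t_b)
        rev = delayed_lag(np.sort(duration - t_a), np.sort(duration - t_b))
        assert fwd == 2 and rev == -2


class TestClassifyEdges:
    def test_same_line_span(self, layout):
        e = ConnectivityEdge("34", "64", 10.0, 0.9, EdgeClass.SAME_LINE, "delayed")
        summary = classify_edges([e], layout)
        assert summary.counts_by_class == {"same_line": 1}
        assert summary.spans["same_line"] == [3]

    def test_somatic_chamber_edges_all_soma_neurite(self, layout):
        from mfnet.geometry import edge_class

        ids = ["14", "15", "25"]
        edges = [
            ConnectivityEdge(a, b, 0.0, 0.9, edge_class(layout, a, b), "short_term")
            for a, b in [("14", "15"), ("14", "25"), ("15", "25")]
        ]
        summary = classify_edges(edges, layout, electrodes=set(ids))
        assert set(summary.counts_by_class) == {"soma_neurite"}
        assert summary.n_edges == 3

    def test_per_electrode_counts_by_compartment(self, layout):
        edges = [
            ConnectivityEdge("44", "54", 0.0, 0.9, EdgeClass.SAME_LINE, "short_term"),
            ConnectivityEdge("44", "45", 0.0, 0.9, EdgeClass.SAME_COLUMN, "short_term"),
        ]
        summary = classify_edges(edges, layout, electrodes={"44", "54", "45", "64"})
        # 4 endpoints in the synaptic chamber over 3 synaptic electrodes
        assert summary.edges_per_electrode_by_compartment["synaptic_chamber"] == pytest.approx(4 / 3)
        assert summary.edges_per_electrode_by_compartment["long_microchannel"] == 0.0


class TestNodeRoles:
    def test_role_definitions(self, layout):
        edges = [
            ConnectivityEdge("14", "34", 10.0, 0.9, EdgeClass.SOMA_NEURITE, "delayed"),
            ConnectivityEdge("14", "44", 15.0, 0.9, EdgeClass.SOMA_NEURITE, "delayed"),
            ConnectivityEdge("64", "25", 10.0, 0.9, EdgeClass.SOMA_NEURITE, "delayed"),
            ConnectivityEdge("25", "34", 10.0, 0.9, EdgeClass.SOMA_NEURITE, "delayed"),
        ]
        roles = node_roles(edges, layout, electrodes={"14", "25", "16", "34", "44", "64"})
        assert roles["14"].role.value == "efferent"
        assert roles["25"].role.value == "mixed"
        assert roles["16"].role.value == "isolated"
        assert roles["34"].role is None  # non-somatic: degrees only
        assert roles["34"].in_degree == 2

    def test_degree_conservation(self, layout):
        rng = np.random.default_rng(1)
        ids = layout.electrode_ids
        edges = []
        for _ in range(30):
            a, b = rng.choice(ids, size=2, replace=False)
            edges.append(ConnectivityEdge(a, b, 10.0, 0.5, EdgeClass.MISALIGNED, "delayed"))
        roles = node_roles(edges, layout)
        assert sum(r.out_degree for r in roles.values()) == 30
        assert sum(r.in_degree for r in roles.values()) == 30


def test_to_networkx_directed_with_attributes(layout):
    edges = [ConnectivityEdge("14", "34", 10.0, 0.9, EdgeClass.SOMA_NEURITE, "delayed", 0.001)]
    g = to_networkx(edges, layout)
    assert g.is_directed()
    assert g["14"]["34"]["delay_ms"] == 10.0
    assert g.nodes["14"]["compartment"] == "somatic_chamber_A"
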