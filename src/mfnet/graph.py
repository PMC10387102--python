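"""Connectivity graphs from significant pairwise correlations.

Two mutually exclusive windows at 5 ms binning:

* short-term: the correlation maximum sits in the central bin
  (|delay| <= 2.5 ms) -- synchrony or direct fast propagation; undirected.
* delayed: the maximum sits at lag 1..max_lag bins (5-25 ms by default) --
  directed propagation from the leading to the lagging electrode, possibly
  through hidden nodes.

Somatic electrodes with only outgoing delayed edges are efferent (output)
nodes; only incoming, afferent (input) nodes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum

import networkx as nx
import numpy as np

from .correlation import CorrelationResult
from .geometry import EdgeClass, ElectrodeLayout, edge_class, edge_span


@dataclass(frozen=True)
class ConnectivityEdge:
    from_electrode: str
    to_electrode: str
    delay_ms: float  # signed; 0 for short-term edges
    strength: float  # c_max
    edge_class: EdgeClass
    window: str  # "short_term" | "delayed"
    p_value: float = float("nan")


class NodeRoleKind(str, Enum):
    EFFERENT = "efferent"
    AFFERENT = "afferent"
    MIXED = "mixed"
    ISOLATED = "isolated"


@dataclass(frozen=True)
class NodeRole:
    electrode_id: str
    role: NodeRoleKind | None  # None for non-somatic electrodes
    in_degree: int
    out_degree: int


def _significant(pc, alpha: float) -> bool:
    return (not pc.degenerate) and np.isfinite(pc.p_value) and pc.p_value < alpha


def short_term_graph(
    cc: CorrelationResult, layout: ElectrodeLayout, alpha: float = 0.01
) -> list[ConnectivityEdge]:
    """Undirected edges for significant pairs maximal in the central bin.

    Stored canonically with from < to; the delay is the central bin (0 ms).
    """
    edges = []
    for (a, b), pc in sorted(cc.pairs.items()):
        if _significant(pc, alpha) and pc.lag_bins == 0:
            edges.append(
                ConnectivityEdge(
                    from_electrode=min(a, b), to_electrode=max(a, b),
                    delay_ms=0.0, strength=pc.c_max,
                    edge_class=edge_class(layout, a, b),
                    window="short_term", p_value=pc.p_value,
                )
            )
    return edges


def delayed_graph(
    cc: CorrelationResult, layout: ElectrodeLayout, alpha: float = 0.01
) -> list[ConnectivityEdge]:
    """Directed edges for significant pairs maximal at |lag| 1..max_lag bins.

    A positive delay between (a, b) means a leads b, so the edge points
    a -> b; short-term maxima (central bin) are excluded.
    """
    edges = []
    for (a, b), pc in sorted(cc.pairs.items()):
        if not _significant(pc, alpha) or pc.lag_bins == 0:
            continue
        if abs(pc.lag_bins) > cc.max_lag_bins:
            continue
        src, dst = (a, b) if pc.lag_bins > 0 else (b, a)
        edges.append(
            ConnectivityEdge(
                from_electrode=src, to_electrode=dst,
                delay_ms=abs(pc.delay_ms), strength=pc.c_max,
                edge_class=edge_class(layout, a, b),
                window="delayed", p_value=pc.p_value,
            )
        )
    return edges


@dataclass
class EdgeClassSummary:
    """Edge counts by geometric class and per-compartment statistics."""

    counts_by_class: dict[str, int]
    edges_per_electrode_by_compartment: dict[str, float]
    spans: dict[str, list[int]]  # per class, correlation length in pitches
    n_edges: int = 0
    extras: dict = field(default_factory=dict)


def classify_edges(
    edges: list[ConnectivityEdge],
    layout: ElectrodeLayout,
    electrodes: set[str] | None = None,
) -> EdgeClassSummary:
    """Summarize edges by class, compartment and span.

    ``edges_per_electrode_by_compartment`` divides the number of edge
    endpoints falling in a compartment by the number of electrodes
    considered there (the ``electrodes`` universe, default: all electrodes
    of the layout).
    """
    universe = set(electrodes) if electrodes is not None else set(layout.electrode_ids)
    class_counts: Counter = Counter()
    endpoint_counts: Counter = Counter()
    spans: dict[str, list[int]] = {}
    for e in edges:
        class_counts[e.edge_class.value] += 1
        spans.setdefault(e.edge_class.value, []).append(
            edge_span(layout, e.from_electrode, e.to_electrode)
        )
        for eid in (e.from_electrode, e.to_electrode):
            endpoint_counts[layout.compartment(eid).value] += 1
    comp_sizes: Counter = Counter(layout.compartment(e).value for e in universe)
    per_electrode = {
        comp: endpoint_counts[comp] / n for comp, n in sorted(comp_sizes.items()) if n > 0
    }
    return EdgeClassSummary(
        counts_by_class=dict(class_counts),
        edges_per_electrode_by_compartment=per_electrode,
        spans=spans,
        n_edges=len(edges),
    )


def node_roles(
    delayed_edges: list[ConnectivityEdge],
    layout: ElectrodeLayout,
    electrodes: set[str] | None = None,
) -> dict[str, NodeRole]:
    """In/out degrees for every node; efferent/afferent roles for somatic ones.

    ``electrodes`` is the node universe (typically the active set); default
    is the set of edge endpoints.
    """
    if electrodes is None:
        electrodes = {e.from_electrode for e in delayed_edges} | {
            e.to_electrode for e in delayed_edges
        }
    out_deg: Counter = Counter()
    in_deg: Counter = Counter()
    for e in delayed_edges:
        out_deg[e.from_electrode] += 1
        in_deg[e.to_electrode] += 1
    roles: dict[str, NodeRole] = {}
    for eid in sorted(electrodes):
        o, i = out_deg[eid], in_deg[eid]
        if layout.is_somatic(eid):
            if o > 0 and i == 0:
                role = NodeRoleKind.EFFERENT
            elif i > 0 and o == 0:
                role = NodeRoleKind.AFFERENT
            elif i > 0 and o > 0:
                role = NodeRoleKind.MIXED
            else:
                role = NodeRoleKind.ISOLATED
        else:
            role = None
        roles[eid] = NodeRole(electrode_id=eid, role=role, in_degree=i, out_degree=o)
    return roles


def to_networkx(
    edges: list[ConnectivityEdge], layout: ElectrodeLayout, directed: bool | None = None
) -> "nx.Graph | nx.DiGraph":
    """Edge list as a networkx graph with electrode positions/compartments."""
    if directed is None:
        directed = any(e.window == "delayed" for e in edges)
    g: nx.Graph = nx.DiGraph() if directed else nx.Graph()
    nodes = {e.from_electrode for e in edges} | {e.to_electrode for e in edges}
    for eid in sorted(nodes):
        el = layout.electrode(eid)
        g.add_node(eid, x=el.x, y=el.y, compartment=layout.compartment(eid).value)
    for e in edges:
        g.add_edge(
            e.from_electrode, e.to_electrode,
            delay_ms=e.delay_ms, strength=e.strength,
            edge_class=e.edge_class.value, window=e.window, p=e.p_value,
        )
    return g
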