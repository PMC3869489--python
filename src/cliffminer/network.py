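"""Cliff networks: isolated vs coordinated cliffs, potency coloring, export.

Cliff-forming compounds are nodes; activity cliffs are edges. A cliff is
*isolated* when its connected component contains exactly its two partners —
neither compound participates in any other cliff. All other cliffs are
*coordinated*: they share compounds with further cliffs, the higher-order
arrangements that carry the most SAR information. Networks are always
per-target; compounds active against different targets are never connected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging
from pathlib import Path

import networkx as nx

from .cliffs import ActivityCliff

log = logging.getLogger(__name__)


@dataclass
class CliffNetwork:
    """Compound-cliff graph for one target set."""

    graph: nx.Graph
    target_id: str
    components: list[frozenset[str]] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def component_of(self, node: str) -> frozenset[str]:
        for comp in self.components:
            if node in comp:
                return comp
        raise KeyError(node)


def build_cliff_network(
    cliffs: list[ActivityCliff],
    pki: dict[str, float] | None = None,
    target_id: str = "",
) -> CliffNetwork:
    """Build the per-target network over exactly the cliff-forming compounds."""
    g = nx.Graph()
    for cliff in sorted(cliffs, key=lambda c: c.pair):
        if cliff.id_a == cliff.id_b:
            continue  # self-loops can never arise from distinct canonical forms
        for cid in cliff.pair:
            if cid not in g:
                node_pki = None
                if pki is not None and cid in pki:
                    node_pki = pki[cid]
                elif cliff.pki_a is not None and cid == cliff.id_a:
                    node_pki = cliff.pki_a
                elif cliff.pki_b is not None and cid == cliff.id_b:
                    node_pki = cliff.pki_b
                g.add_node(cid, pki=node_pki)
        if not g.has_edge(cliff.id_a, cliff.id_b):
            g.add_edge(cliff.id_a, cliff.id_b, delta_pki=cliff.delta_pki, mode=cliff.mode)
    comps = [frozenset(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: min(c))
    return CliffNetwork(graph=g, target_id=target_id, components=comps)


@dataclass
class IsolationSummary:
    n_cliffs: int
    n_isolated: int
    n_coordinated: int

    @property
    def isolated_pct(self) -> float | None:
        if self.n_cliffs == 0:
            return None
        return 100.0 * self.n_isolated / self.n_cliffs

    @property
    def coordinated_pct(self) -> float | None:
        if self.n_cliffs == 0:
            return None
        return 100.0 * self.n_coordinated / self.n_cliffs


def classify_isolated_coordinated(
    network: CliffNetwork, cliffs: list[ActivityCliff]
) -> IsolationSummary:
    """Label each cliff isolated (2-node component) or coordinated.

    Sets ``cliff.isolated`` in place and returns the census. For a non-empty
    cliff set the isolated and coordinated percentages sum to 100.
    """
    size_of = {}
    for comp in network.components:
        for node in comp:
            size_of[node] = len(comp)
    n_isolated = 0
    for cliff in cliffs:
        cliff.isolated = size_of[cliff.id_a] == 2
        n_isolated += cliff.isolated
    return IsolationSummary(
        n_cliffs=len(cliffs), n_isolated=n_isolated, n_coordinated=len(cliffs) - n_isolated
    )


def _ramp(t: float) -> str:
    """Linear red -> yellow -> green ramp on t in [0, 1], as a hex color."""
    t = min(1.0, max(0.0, t))
    if t <= 0.5:
        r, g = 255, round(510 * t)          # red to yellow
    else:
        r, g = round(510 * (1.0 - t)), 255  # yellow to green
    return f"#{r:02x}{g:02x}00"


def potency_color_attributes(network: CliffNetwork) -> dict[str, str]:
    """Per-node hex colors: lowest pKi red, midpoint yellow, highest green.

    Normalization is per network (colors are comparable within one target
    set, not across sets). A degenerate all-equal network maps every node to
    the mid color with a warning.
    """
    pkis = nx.get_node_attributes(network.graph, "pki")
    if any(v is None for v in pkis.values()) or len(pkis) < network.n_nodes:
        raise ValueError("all nodes need a pKi value for potency coloring")
    if not pkis:
        return {}
    lo, hi = min(pkis.values()), max(pkis.values())
    if hi == lo:
        log.warning("all nodes share one pKi; coloring entire network mid-range yellow")
        colors = {cid: _ramp(0.5) for cid in pkis}
    else:
        colors = {cid: _ramp((v - lo) / (hi - lo)) for cid, v in pkis.items()}
    nx.set_node_attributes(network.graph, colors, "color")
    return colors


def export_graphml(network: CliffNetwork, path: str | Path) -> None:
    """GraphML with compound_id/pKi/color node attributes and cliff edge attributes."""
    g = nx.Graph()
    for node in sorted(network.graph.nodes):
        data = network.graph.nodes[node]
        attrs = {"compound_id": node}
        if data.get("pki") is not None:
            attrs["pKi"] = float(data["pki"])
        if data.get("color") is not None:
            attrs["color"] = data["color"]
        g.add_node(node, **attrs)
    for a, b in sorted(map(tuple, map(sorted, network.graph.edges))):
        data = network.graph.edges[a, b]
        attrs = {"mode": data.get("mode", "")}
        if data.get("delta_pki") is not None:
            attrs["delta_pKi"] = float(data["delta_pki"])
        g.add_edge(a, b, **attrs)
    nx.write_graphml(g, str(path), named_key_ids=True)


def export_edge_list(network: CliffNetwork, path: str | Path) -> None:
    """Plain CSV edge list (compound_id_1, compound_id_2, delta_pKi, mode)."""
    lines = ["compound_id_1,compound_id_2,delta_pKi,mode"]
    for a, b in sorted(map(tuple, map(sorted, network.graph.edges))):
        data = network.graph.edges[a, b]
        delta = data.get("delta_pki")
        lines.append(f"{a},{b},{'' if delta is None else repr(float(delta))},{data.get('mode', '')}")
    Path(path).write_text("\n".join(lines) + "\n")
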