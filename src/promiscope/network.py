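"""Promiscuity-cliff network, hubs and alternating pathways.

Nodes are compounds (annotated with PD and a multiclass flag), edges are
pairwise promiscuity-cliff relationships.  The graph is bipartite by
construction — every edge joins a highly promiscuous compound to a
non-promiscuous or inactive analog — and this is checked, not assumed.

Promiscuity hubs are multiclass ligands forming at least ``min_degree``
(default 10) cliff relationships; an alternative mode defines hubs as nodes
with an above-average number of relationships.  Promiscuity-cliff pathways
are maximal simple paths; bipartiteness makes them alternate strictly
between the promiscuous and non-promiscuous side.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx

from promiscope.mmp import PromiscuityCliff

PROMISCUOUS = "promiscuous"
PARTNER = "partner"


class BipartitenessError(ValueError):
    """A cliff edge or node assignment violates the two-sided structure of
    the network; indicates an upstream bug."""


@dataclass
class PCNetwork:
    """Bipartite promiscuity-cliff network (thin wrapper over an undirected
    networkx graph with node attributes ``pd``, ``side``,
    ``is_multiclass``)."""

    graph: nx.Graph

    def check_bipartite(self) -> None:
        for u, v in self.graph.edges:
            su = self.graph.nodes[u]["side"]
            sv = self.graph.nodes[v]["side"]
            if su == sv:
                raise BipartitenessError(
                    f"edge ({u}, {v}) joins two {su} nodes"
                )

    def components(self) -> list[set[str]]:
        """PC clusters: disjoint segments of the network."""
        return [set(c) for c in nx.connected_components(self.graph)]

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_pc_network(
    cliffs: Iterable[PromiscuityCliff],
    multiclass_ids: set[str] | None = None,
) -> PCNetwork:
    """Build the deduplicated cliff network.

    Duplicate cliff records collapse to a single edge; self-loops cannot
    arise (a cliff has distinct members by construction).  A compound
    appearing as the promiscuous member of one cliff and the partner of
    another violates bipartiteness and raises.  When ``multiclass_ids`` is
    not given, every promiscuous-side node is treated as a multiclass
    ligand.
    """
    g = nx.Graph()
    for cliff in cliffs:
        for cid, side, pd in (
            (cliff.promiscuous_id, PROMISCUOUS, cliff.pd_promiscuous),
            (cliff.partner_id, PARTNER, cliff.pd_partner),
        ):
            if cid in g.nodes and g.nodes[cid]["side"] != side:
                raise BipartitenessError(
                    f"compound {cid} appears on both sides of the network"
                )
            is_mc = (
                side == PROMISCUOUS
                if multiclass_ids is None
                else cid in multiclass_ids
            )
            g.add_node(cid, pd=pd, side=side, is_multiclass=is_mc)
        g.add_edge(
            cliff.promiscuous_id,
            cliff.partner_id,
            transformation=cliff.mmp.transformation,
            shared_tested=cliff.shared_tested,
        )
    net = PCNetwork(graph=g)
    net.check_bipartite()
    return net


def find_promiscuity_hubs(
    network: PCNetwork, min_degree: int = 10, mode: str = "fixed"
) -> set[str]:
    """Multiclass-ligand nodes with many cliff relationships.

    ``mode="fixed"`` (primary): degree >= ``min_degree`` (default 10).
    ``mode="above_average"``: degree strictly greater than the network's
    mean degree.
    """
    g = network.graph
    if mode == "fixed":
        threshold = min_degree
        qualifies = lambda d: d >= threshold  # noqa: E731
    elif mode == "above_average":
        if g.number_of_nodes() == 0:
            return set()
        mean_deg = sum(d for _, d in g.degree) / g.number_of_nodes()
        qualifies = lambda d: d > mean_deg  # noqa: E731
    else:
        raise ValueError(f"unknown hub mode {mode!r}")
    return {
        n
        for n, d in g.degree
        if g.nodes[n]["is_multiclass"] and qualifies(d)
    }


@dataclass(frozen=True)
class PCPathway:
    """A maximal simple path alternating between the promiscuous and
    non-promiscuous side."""

    nodes: tuple[str, ...]
    sides: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.nodes) != len(set(self.nodes)):
            raise ValueError("pathway nodes must be distinct")
        for a, b in zip(self.sides, self.sides[1:]):
            if a == b:
                raise ValueError("pathway sides must strictly alternate")

    @property
    def n_promiscuous(self) -> int:
        return sum(1 for s in self.sides if s == PROMISCUOUS)

    @property
    def n_partner(self) -> int:
        return sum(1 for s in self.sides if s == PARTNER)

    def __len__(self) -> int:
        return len(self.nodes)


def extract_pathways(
    network: PCNetwork, min_length: int = 3, max_paths: int = 10_000
) -> list[PCPathway]:
    """Enumerate maximal simple paths with at least ``min_length`` nodes.

    A path is maximal when neither endpoint has a neighbor outside the
    path.  Enumeration is depth-first with lexicographic neighbor ordering,
    deduplicated across the two orientations, and capped at ``max_paths``
    recorded paths for safety on dense networks.
    """
    g = network.graph
    results: set[tuple[str, ...]] = set()

    def extend(path: list[str], visited: set[str]) -> None:
        if len(results) >= max_paths:
            return
        nbrs = [n for n in sorted(g.neighbors(path[-1])) if n not in visited]
        if not nbrs:
            # forward-maximal; require backward maximality too
            if len(path) >= min_length and all(
                n in visited for n in g.neighbors(path[0])
            ):
                fwd = tuple(path)
                rev = tuple(reversed(path))
                results.add(min(fwd, rev))
            return
        for n in nbrs:
            visited.add(n)
            path.append(n)
            extend(path, visited)
            path.pop()
            visited.remove(n)

    for start in sorted(g.nodes):
        extend([start], {start})

    pathways = [
        PCPathway(
            nodes=nodes,
            sides=tuple(g.nodes[n]["side"] for n in nodes),
        )
        for nodes in sorted(results)
    ]
    return pathways
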