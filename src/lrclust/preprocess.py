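"""Graph simplification applied before clustering.

A single read that is the only link between otherwise unrelated groups of
reads (a chimera, a shared repeat) shows up as an articulation point of the
similarity graph.  Preprocessing disconnects every articulation point of
the raw graph in one pass — the node keeps its identity and is later
reported as a singleton cluster — then the graph decomposes into connected
components that are clustered independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

__all__ = [
    "ComponentDecomposition",
    "articulation_points",
    "disconnect_articulation_points",
    "connected_components",
]


@dataclass
class ComponentDecomposition:
    """Connected components of the (possibly preprocessed) graph.

    ``components`` are maximal connected node sets ordered by smallest
    contained node; ``singleton_pool`` holds the nodes whose edges were
    severed by preprocessing (a subset of the singleton components).
    """

    components: list[frozenset[int]]
    singleton_pool: frozenset[int] = field(default_factory=frozenset)


def articulation_points(graph: nx.Graph) -> set[int]:
    """Nodes whose removal increases the number of connected components.

    Found with the standard linear-time DFS (Hopcroft–Tarjan, as exposed
    by networkx).
    """
    return set(nx.articulation_points(graph))


def disconnect_articulation_points(graph: nx.Graph) -> tuple[nx.Graph, frozenset[int]]:
    """Remove every edge incident to an articulation point of the input.

    All articulation points are determined on the *input* graph and their
    incident edges removed in one pass (no recursion on articulation
    points that the removals may create).  The nodes themselves stay in
    the graph, now isolated, and are returned as the singleton pool.
    """
    aps = articulation_points(graph)
    out = graph.copy()
    for node in aps:
        out.remove_edges_from(list(out.edges(node)))
    return out, frozenset(aps)


def connected_components(graph: nx.Graph) -> ComponentDecomposition:
    """Maximal connected components, ordered by smallest contained node."""
    comps = sorted((frozenset(c) for c in nx.connected_components(graph)), key=min)
    return ComponentDecomposition(components=comps)
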