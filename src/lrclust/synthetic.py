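"""Planted-partition generator emulating long-read similarity graphs.

Every gene contributes a clique of its reads; real overlap graphs deviate
from that ideal in three ways, each modelled here with independent
edge-level noise:

* missed overlaps — each intra-cluster edge is kept with probability
  ``p_within``;
* spurious overlaps (repeats, paralogy) — extra edges between uniformly
  chosen nodes of distinct clusters, added until they make up the target
  fraction of all edges;
* repeat-like hub reads — optional extra nodes attached by a single edge
  to each of several clusters, reproducing the articulation-point
  pathology that graph preprocessing targets.

Cluster sizes are drawn from four size bins mirroring expression
quartiles (<=5, 5-10, 10-50, >=50 reads per gene).  Everything is fully
determined by ``rng_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np

from .graph_io import ClusterAssignment, SimilarityGraph

__all__ = ["SimulationConfig", "SyntheticInstance", "sample_sizes", "simulate"]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic similarity graph.

    size_bins are inclusive (lo, hi) ranges; a bin is picked by weight,
    then the size uniformly within it.  The top bin is capped (default
    200 reads) so instances stay desk-sized.  Set a bin's low edge to 1
    to allow singleton truth clusters.
    """

    n_clusters: int = 100
    size_bins: tuple[tuple[int, int], ...] = ((2, 5), (6, 10), (11, 50), (51, 200))
    bin_weights: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    p_within: float = 0.9
    spurious_edge_fraction: float = 0.01
    n_hubs: int = 0
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if not 0.0 <= self.p_within <= 1.0:
            raise ValueError("p_within must be in [0, 1]")
        if not 0.0 <= self.spurious_edge_fraction < 1.0:
            raise ValueError("spurious_edge_fraction must be in [0, 1)")
        if len(self.size_bins) != len(self.bin_weights):
            raise ValueError("size_bins and bin_weights must have equal length")
        if any(lo < 1 or hi < lo for lo, hi in self.size_bins):
            raise ValueError("size bins must satisfy 1 <= lo <= hi")
        if any(w < 0 for w in self.bin_weights) or sum(self.bin_weights) <= 0:
            raise ValueError("bin weights must be non-negative and not all zero")
        if self.spurious_edge_fraction > 0 and self.n_clusters < 2:
            raise ValueError(
                "spurious edges require at least two clusters")
        if self.n_hubs > 0 and self.n_clusters < 2:
            raise ValueError("hub nodes require at least two clusters")


@dataclass
class SyntheticInstance:
    """A simulated similarity graph together with its planted truth."""

    graph: nx.Graph
    truth: ClusterAssignment
    config: SimulationConfig

    def similarity_graph(self) -> SimilarityGraph:
        return SimilarityGraph(graph=self.graph,
                               name_to_index={str(n): n for n in self.graph.nodes})


def sample_sizes(config: SimulationConfig,
                 rng: np.random.Generator) -> list[int]:
    """Draw ``n_clusters`` cluster sizes: bin by weight, size uniform in bin."""
    config.validate()
    weights = np.asarray(config.bin_weights, dtype=float)
    weights = weights / weights.sum()
    bins = rng.choice(len(config.size_bins), size=config.n_clusters, p=weights)
    sizes = []
    for b in bins:
        lo, hi = config.size_bins[b]
        sizes.append(int(rng.integers(lo, hi + 1)))
    return sizes


def simulate(config: SimulationConfig) -> SyntheticInstance:
    """Generate one planted-partition instance (graph + ground truth).

    Per cluster a clique is laid down with each edge kept with
    probability ``p_within``; spurious inter-cluster edges are then added
    until they reach ``spurious_edge_fraction`` of all edges; hub nodes
    (singletons in the truth) are wired by one edge to each of >= 2
    distinct clusters.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    sizes = sample_sizes(config, rng)

    graph = nx.Graph()
    clusters: list[frozenset[int]] = []
    cluster_of: dict[int, int] = {}
    next_id = 0
    for ci, size in enumerate(sizes):
        members = list(range(next_id, next_id + size))
        next_id += size
        graph.add_nodes_from(members)
        for m in members:
            cluster_of[m] = ci
        clusters.append(frozenset(members))
        for a_idx in range(size):
            for b_idx in range(a_idx + 1, size):
                if rng.random() < config.p_within:
                    graph.add_edge(members[a_idx], members[b_idx])

    n_intra = graph.number_of_edges()
    f = config.spurious_edge_fraction
    n_clustered = next_id
    if f > 0 and n_intra > 0:
        target = int(round(f / (1.0 - f) * n_intra))
        added = 0
        # rejection sampling over node pairs from distinct clusters
        while added < target:
            u = int(rng.integers(0, n_clustered))
            v = int(rng.integers(0, n_clustered))
            if u == v or cluster_of[u] == cluster_of[v]:
                continue
            if graph.has_edge(u, v):
                continue
            graph.add_edge(u, v)
            added += 1

    for _ in range(config.n_hubs):
        hub = next_id
        next_id += 1
        graph.add_node(hub)
        k = int(rng.integers(2, min(4, config.n_clusters) + 1))
        chosen = rng.choice(config.n_clusters, size=k, replace=False)
        for ci in sorted(int(c) for c in chosen):
            anchor = int(rng.choice(sorted(clusters[ci])))
            graph.add_edge(hub, anchor)
        clusters.append(frozenset({hub}))

    truth = ClusterAssignment(clusters).canonical()
    return SyntheticInstance(graph=graph, truth=truth, config=config)
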