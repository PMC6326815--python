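"""Seed-and-refine clustering of a read-similarity graph.

The model: in a perfect similarity graph every expressed gene appears as a
clique of its reads, so cluster quality is measured by *cliqueness* — the
local clustering coefficient (ClCo) — rather than modularity.  For one
connected component the algorithm

1. computes each node's degree and ClCo,
2. treats every distinct (rounded, non-zero) ClCo value as a candidate
   cutoff; for each cutoff, nodes with ClCo above it found communities
   together with their direct neighbourhood (a degree guard keeps
   star-like hubs from seeding),
3. refines intersecting communities pairwise — merging them when the
   aggregated ClCo of the union stays above the cutoff, otherwise
   splitting by assigning the intersection to the side that costs the
   fewer edge removals (a minimum-cut move),
4. keeps, across all cutoffs, the partition whose total cut (edges not
   internal to any community) is smallest.

Exact minimum k-cut is NP-hard; this is the heuristic the package exists
for.  Everything is deterministic: fixed orderings, no randomness.
"""

from __future__ import annotations

import heapq
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from math import ceil
from typing import Iterable, Literal, Mapping, Optional, Sequence

import networkx as nx
import numpy as np

from .graph_io import ClusterAssignment, SimilarityGraph
from .preprocess import connected_components, disconnect_articulation_points

__all__ = [
    "NodeStats",
    "SeedThresholds",
    "Community",
    "Partition",
    "CutoffSchedule",
    "Resolution",
    "ClusterConfig",
    "local_clco",
    "node_stats",
    "seed_thresholds",
    "cutoff_schedule",
    "select_seeds",
    "seed_communities",
    "union_clco",
    "delta_cc",
    "resolve_pair",
    "generate_partition",
    "best_partition",
    "cluster_graph",
]


# ---------------------------------------------------------------------------
# types

@dataclass(frozen=True)
class NodeStats:
    """Per-node degree and local clustering coefficient.

    ``clco`` is rounded to the schedule's precision; ``triangles`` is the
    raw number of edges among the node's neighbours (kept so a seed
    community's internal edge count is available in O(1):
    E({n} ∪ N(n)) = deg(n) + triangles(n)).
    """

    degree: int
    clco: float
    triangles: int = 0


@dataclass(frozen=True)
class SeedThresholds:
    """Degree/ClCo guard thresholds (nearest-rank percentiles).

    ``theta1``: 99th percentile of observed degrees; ``theta2``: 1st
    percentile of observed ClCo.  A node whose ClCo lies strictly between
    the current cutoff and theta2 while its degree exceeds theta1 is a
    star-like pattern and may not seed a community.
    """

    theta1: int
    theta2: float


@dataclass
class Community:
    """A seed node plus its member set; the unit merged/split in refinement.

    ``members`` may be a frozenset until the community first absorbs
    another one (copy-on-write inside the refinement engine).
    """

    seed: int
    members: set[int] | frozenset[int]
    _edges: Optional[int] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("community members must be non-empty")
        if self.seed not in self.members:
            raise ValueError("community seed must belong to its members")


@dataclass(frozen=True)
class Partition:
    """Disjoint communities covering one connected component.

    ``cut_size`` is the number of component edges not internal to any
    community; ``cutoff`` is the ClCo cutoff that generated the partition
    (None for the degenerate single-community fallback).
    """

    communities: tuple[frozenset[int], ...]
    cut_size: int
    cutoff: Optional[float]


@dataclass(frozen=True)
class CutoffSchedule:
    """Strictly decreasing, rounded, non-zero ClCo values to sweep."""

    values: tuple[float, ...]
    rounding: int = 2
    max_values: int = 100


@dataclass(frozen=True)
class Resolution:
    """Outcome of resolving one intersecting community pair.

    ``first``/``second`` are the updated communities in the positional
    roles of the inputs (None if dissolved); ``removed_edges`` lists the
    working-graph edges severed by a split.  ``added``/``left_first``/
    ``left_second`` record the membership deltas of the two positions so
    callers can maintain node-to-community indexes incrementally.
    """

    action: Literal["merge", "split"]
    first: Optional[Community]
    second: Optional[Community]
    removed_edges: tuple[tuple[int, int], ...] = ()
    added: tuple[int, ...] = ()
    left_first: tuple[int, ...] = ()
    left_second: tuple[int, ...] = ()

    @property
    def edges_removed(self) -> int:
        return len(self.removed_edges)


@dataclass(frozen=True)
class ClusterConfig:
    """Tunable surface of the clustering pipeline.

    rounding: decimal places kept when rounding ClCo values (collapses
        noise-level differences between cutoffs).
    max_cutoffs: cap on the number of cutoffs swept per component.
    preprocess: disconnect articulation points before clustering.
    percentile_scope: compute the seed-guard percentiles per connected
        component (default) or once over the whole graph.
    threads: number of worker threads over components (results are
        independent of this value).
    per_node_split: assign intersection nodes one by one instead of as a
        block when splitting (off by default).
    """

    rounding: int = 2
    max_cutoffs: int = 100
    preprocess: bool = True
    percentile_scope: Literal["component", "global"] = "component"
    threads: int = 1
    per_node_split: bool = False


# ---------------------------------------------------------------------------
# per-node statistics

def local_clco(graph: nx.Graph, node: int) -> float:
    """Local clustering coefficient of ``node`` (unrounded).

    For degree >= 2 this is the fraction of realised edges among the
    node's neighbours; nodes of degree 0 and 1 have a ClCo of 1.
    """
    if node not in graph:
        raise KeyError(f"node {node} not in graph")
    nbrs = set(graph.adj[node])
    nbrs.discard(node)
    deg = len(nbrs)
    if deg <= 1:
        return 1.0
    triangles = sum(len(nbrs & graph.adj[v].keys()) for v in nbrs) // 2
    return 2.0 * triangles / (deg * (deg - 1))


def node_stats(graph: nx.Graph, rounding: int = 2) -> dict[int, NodeStats]:
    """Degree, rounded ClCo and neighbour-edge count for every node."""
    adj = {u: set(graph.adj[u]) - {u} for u in graph.nodes}
    stats: dict[int, NodeStats] = {}
    for u, nbrs in adj.items():
        deg = len(nbrs)
        if deg <= 1:
            stats[u] = NodeStats(degree=deg, clco=1.0, triangles=0)
            continue
        tri = sum(len(nbrs & adj[v]) for v in nbrs) // 2
        clco = round(2.0 * tri / (deg * (deg - 1)), rounding)
        stats[u] = NodeStats(degree=deg, clco=clco, triangles=tri)
    return stats


def _nearest_rank(sorted_values: Sequence, pct: float):
    """Nearest-rank percentile on an ascending sequence (pct in [0, 100])."""
    n = len(sorted_values)
    rank = max(1, ceil(pct / 100.0 * n))
    return sorted_values[min(rank, n) - 1]


def seed_thresholds(stats: Mapping[int, NodeStats]) -> SeedThresholds:
    """Guard thresholds from the observed degree/ClCo distributions."""
    if not stats:
        raise ValueError("cannot compute thresholds from empty stats")
    degrees = sorted(s.degree for s in stats.values())
    clcos = sorted(s.clco for s in stats.values())
    return SeedThresholds(theta1=_nearest_rank(degrees, 99.0),
                          theta2=_nearest_rank(clcos, 1.0))


def cutoff_schedule(stats: Mapping[int, NodeStats], rounding: int = 2,
                    max_values: int = 100) -> CutoffSchedule:
    """Distinct rounded non-zero ClCo values, sorted decreasing.

    If more than ``max_values`` remain, ranks are subsampled uniformly,
    always keeping the largest and smallest value.
    """
    values = sorted({round(s.clco, rounding) for s in stats.values()
                     if round(s.clco, rounding) > 0}, reverse=True)
    if len(values) > max_values:
        idx = np.round(np.linspace(0, len(values) - 1, max_values)).astype(int)
        values = [values[i] for i in sorted(set(int(i) for i in idx))]
    return CutoffSchedule(values=tuple(values), rounding=rounding,
                          max_values=max_values)


def select_seeds(stats: Mapping[int, NodeStats], thresholds: SeedThresholds,
                 cutoff: float) -> list[int]:
    """Nodes eligible to found a community at this cutoff.

    A node seeds iff its ClCo >= cutoff, except for the star-pattern
    guard: nodes with ClCo strictly inside (cutoff, theta2) whose degree
    exceeds theta1 are excluded.  Order: decreasing degree, then
    decreasing ClCo, then increasing node index.
    """
    return _filter_seeds(_rank_nodes(stats), stats, thresholds, cutoff)


def _rank_nodes(stats: Mapping[int, NodeStats]) -> list[int]:
    return sorted(stats, key=lambda n: (-stats[n].degree, -stats[n].clco, n))


def _filter_seeds(ranked: Sequence[int], stats: Mapping[int, NodeStats],
                  thresholds: SeedThresholds, cutoff: float) -> list[int]:
    t1, t2 = thresholds.theta1, thresholds.theta2
    out = []
    for n in ranked:
        s = stats[n]
        if s.clco >= cutoff and not (cutoff < s.clco < t2 and s.degree > t1):
            out.append(n)
    return out


# ---------------------------------------------------------------------------
# set-level cliqueness helpers

def _internal_edges(adj: Mapping[int, set[int]], members: set[int]) -> int:
    return sum(len(adj[u] & members) for u in members) // 2


def _set_clco_from(edges: int, n: int) -> float:
    if n < 2:
        return 1.0
    return 2.0 * edges / (n * (n - 1))


def _adj_dict(graph: nx.Graph) -> dict[int, set[int]]:
    return {u: set(graph.adj[u]) - {u} for u in graph.nodes}


def _community_edges(comm: Community, adj: Mapping[int, set[int]]) -> int:
    if comm._edges is None:
        comm._edges = _internal_edges(adj, comm.members)
    return comm._edges


def union_clco(graph: nx.Graph, a: Iterable[int], b: Iterable[int]) -> float:
    """Aggregated clustering coefficient of the union of two node sets:
    2 E(A ∪ B) / (|A ∪ B| (|A ∪ B| − 1)) with E counting edges internal
    to the union.  Raises for unions of fewer than two nodes."""
    union = set(a) | set(b)
    if len(union) < 2:
        raise ValueError("union of communities must contain at least 2 nodes")
    adj = {u: set(graph.adj[u]) - {u} for u in union if u in graph}
    edges = sum(len(adj.get(u, set()) & union) for u in union) // 2
    return _set_clco_from(edges, len(union))


def delta_cc(graph: nx.Graph, before: Iterable[int], after: Iterable[int]) -> float:
    """Gain in set-level cliqueness from growing ``before`` into ``after``
    (the merge tie-break criterion).  ``before`` must be a subset of
    ``after``; sets with fewer than two nodes have coefficient 1."""
    before, after = set(before), set(after)
    if not before <= after:
        raise ValueError("'before' must be a subset of 'after'")
    adj = {u: set(graph.adj[u]) - {u} for u in after if u in graph}
    cc_after = _set_clco_from(
        sum(len(adj.get(u, set()) & after) for u in after) // 2, len(after))
    cc_before = _set_clco_from(
        sum(len(adj.get(u, set()) & before) for u in before) // 2, len(before))
    return cc_after - cc_before


# ---------------------------------------------------------------------------
# community construction and pair resolution

def seed_communities(graph: nx.Graph, seeds: Sequence[int],
                     stats: Optional[Mapping[int, NodeStats]] = None) -> list[Community]:
    """One community per seed: the seed plus its direct neighbourhood.

    Communities with identical member sets are deduplicated, keeping the
    earliest seed in order.  When ``stats`` is given, internal edge
    counts are seeded from it without touching the adjacency again.
    """
    out: list[Community] = []
    seen: set[frozenset[int]] = set()
    for seed in seeds:
        if seed not in graph:
            raise KeyError(f"seed {seed} not in graph")
        members = {seed} | set(graph.adj[seed])
        members_key = frozenset(members)
        if members_key in seen:
            continue
        seen.add(members_key)
        edges = None
        if stats is not None and seed in stats:
            edges = stats[seed].degree + stats[seed].triangles
        out.append(Community(seed=seed, members=members, _edges=edges))
    return out


def _reseat(seed: int, members: set[int]) -> int:
    """Deterministic replacement seed when the old one left the community."""
    return seed if seed in members else min(members)


def _resolve(adj: dict[int, set[int]], c1: Community, c2: Community,
             cutoff: float, per_node: bool = False) -> Resolution:
    """Resolve one intersecting pair on the working adjacency.

    Private engine contract: the adjacency is mutated in place when edges
    are cut, and the *first* community's member set may be reused
    (aliased) by the returned communities — callers must treat both
    inputs as consumed.  All set arithmetic iterates the smaller side so
    one huge community never makes a resolution quadratic.
    """
    a, b = c1.members, c2.members
    inter = (a & b) if len(a) <= len(b) else (b & a)
    if not inter:
        raise ValueError("communities do not intersect")
    la, lb, li = len(a), len(b), len(inter)
    ea = _community_edges(c1, adj)
    eb = _community_edges(c2, adj)
    # union cliqueness via the smaller difference side:
    # E(A ∪ B) = E(base) + cross(D, base) + E(D) with D the other side's extra
    # E(A ∪ B) = E(base) + cross(D, base) + E(D), D the smaller extra side
    if lb <= la:
        diff = b - a
        e_union = ea + sum(2 * len(adj[u] & a) + len(adj[u] & diff)
                           for u in diff) // 2
    else:
        diff = a - b
        e_union = eb + sum(2 * len(adj[u] & b) + len(adj[u] & diff)
                           for u in diff) // 2
    n_union = la + lb - li
    if _set_clco_from(e_union, n_union) >= cutoff:
        if lb <= la:
            added = tuple(diff)  # nodes new to c1
            members = set(a) if type(a) is frozenset else a
            members.update(added)
        else:
            added = tuple(b - a)
            members = set(b)
            members.update(a)
        merged = Community(seed=c1.seed, members=members, _edges=e_union)
        return Resolution("merge", merged, None, added=added)

    if per_node:
        return _resolve_per_node(adj, c1, c2, inter, a - inter, b - inter)

    e_int: Optional[int] = None

    def edges_inter() -> int:
        nonlocal e_int
        if e_int is None:
            e_int = _internal_edges(adj, inter)
        return e_int

    def rest_cross(members: set[int], lm: int) -> int:
        """Edges between the intersection and members \\ intersection."""
        if lm - li <= li:
            rest = members - inter
            return sum(len(adj[u] & inter) for u in rest)
        return sum(len(adj[u] & members) for u in inter) - 2 * edges_inter()

    e1 = rest_cross(a, la)
    e2 = rest_cross(b, lb)
    if e1 != e2:
        winner_is_first = e1 > e2
    else:
        er_a = ea - edges_inter() - e1  # E(A \ I)
        er_b = eb - edges_inter() - e2
        d1 = _set_clco_from(ea, la) - _set_clco_from(er_a, la - li)
        d2 = _set_clco_from(eb, lb) - _set_clco_from(er_b, lb - li)
        if d1 != d2:
            winner_is_first = d1 > d2
        else:
            winner_is_first = c1.seed <= c2.seed

    if winner_is_first:
        win_c, win_members, e_win = c1, a, ea
        lose_c, lose_members, e_lose = c2, b, eb
    else:
        win_c, win_members, e_win = c2, b, eb
        lose_c, lose_members, e_lose = c1, a, ea
    lose_rest = lose_members - inter
    removed = []
    if li <= len(lose_rest):
        for u in inter:
            for v in adj[u] & lose_rest:
                removed.append((u, v))
    else:
        for v in lose_rest:
            for u in adj[v] & inter:
                removed.append((u, v))
    for u, v in removed:
        adj[u].discard(v)
        adj[v].discard(u)
    winner = Community(seed=win_c.seed, members=win_members, _edges=e_win)
    loser = None
    if lose_rest:
        if len(lose_rest) <= li:
            e_rest = _internal_edges(adj, lose_rest)  # unaffected by the removals
        else:
            e_rest = e_lose - edges_inter() - len(removed)
        loser = Community(seed=_reseat(lose_c.seed, lose_rest),
                          members=lose_rest, _edges=e_rest)
    moved = tuple(inter)
    if winner_is_first:
        return Resolution("split", winner, loser, tuple(removed),
                          left_second=moved)
    return Resolution("split", loser, winner, tuple(removed),
                      left_first=moved)


def _resolve_per_node(adj: dict[int, set[int]], c1: Community, c2: Community,
                      inter: set[int], a_rest: set[int],
                      b_rest: set[int]) -> Resolution:
    """Optional finer split: each intersection node goes to the side it has
    more edges to (ties toward the smaller-seed community)."""
    to_first: set[int] = set()
    to_second: set[int] = set()
    first_on_tie = c1.seed <= c2.seed
    for u in sorted(inter):
        na = len(adj[u] & a_rest)
        nb = len(adj[u] & b_rest)
        if na > nb or (na == nb and first_on_tie):
            to_first.add(u)
        else:
            to_second.add(u)
    new_a = a_rest | to_first
    new_b = b_rest | to_second
    removed = []
    for u in to_first:
        for v in adj[u] & new_b:
            removed.append((u, v))
    for u in to_second:
        for v in adj[u] & a_rest:
            removed.append((u, v))
    for u, v in removed:
        adj[u].discard(v)
        adj[v].discard(u)
    first = Community(seed=_reseat(c1.seed, new_a), members=new_a) if new_a else None
    second = Community(seed=_reseat(c2.seed, new_b), members=new_b) if new_b else None
    return Resolution("split", first, second, tuple(removed),
                      left_first=tuple(to_second), left_second=tuple(to_first))


def resolve_pair(graph: nx.Graph, c1: Community, c2: Community, cutoff: float,
                 per_node: bool = False) -> Resolution:
    """Merge or split one intersecting community pair on ``graph``.

    The union is merged when its aggregated ClCo reaches the cutoff;
    otherwise the intersection block joins the side it shares more edges
    with (ties broken by the larger cliqueness gain, then by the smaller
    seed index) and the edges to the losing side are removed from
    ``graph`` (the working graph) and counted.
    """
    adj = _adj_dict(graph)
    res = _resolve(adj, Community(c1.seed, set(c1.members)),
                   Community(c2.seed, set(c2.members)), cutoff, per_node)
    graph.remove_edges_from(res.removed_edges)
    return res


# ---------------------------------------------------------------------------
# partition generation

def _bits(x: int):
    """Indexes of the set bits of ``x``, ascending."""
    while x:
        lsb = x & -x
        yield lsb.bit_length() - 1
        x ^= lsb


def _bitmask(ids: Iterable[int], nbytes: int) -> int:
    ba = bytearray(nbytes)
    for v in ids:
        ba[v >> 3] |= 1 << (v & 7)
    return int.from_bytes(ba, "little")


class _ComponentEngine:
    """Bitset refinement engine for one connected component.

    Node sets — community memberships and adjacency rows — are Python
    integers used as bitmasks over component-local node ids, so the set
    algebra of the refinement loop (intersections, differences, edge
    counting via ``bit_count``) runs at machine-word speed.  Local ids
    follow ascending node order, which keeps every tie-break identical to
    the set-based definitions.  One engine instance serves the whole
    cutoff schedule; the adjacency is restored after every partition.
    """

    def __init__(self, component: nx.Graph,
                 stats: Mapping[int, NodeStats]) -> None:
        self.nodes = sorted(component.nodes)  # local id -> original node
        pos = {u: k for k, u in enumerate(self.nodes)}
        n = self.n = len(self.nodes)
        nbytes = (n >> 3) + 1
        self.nbrs = [sorted(pos[v] for v in component.adj[u] if v != u)
                     for u in self.nodes]
        self.amask = [_bitmask(nb, nbytes) for nb in self.nbrs]
        self.deg = [stats[u].degree for u in self.nodes]
        self.clco = [stats[u].clco for u in self.nodes]
        # E({s} ∪ N(s)) = deg(s) + edges among the neighbours
        self.edges0 = [stats[u].degree + stats[u].triangles
                       for u in self.nodes]
        self.neigh_mask = [self.amask[k] | (1 << k) for k in range(n)]
        self.ranked = sorted(range(n),
                             key=lambda k: (-self.deg[k], -self.clco[k], k))
        self.total_edges = component.number_of_edges()
        self.full = (1 << n) - 1 if n else 0

    def partition(self, thresholds: SeedThresholds, cutoff: float,
                  per_node_split: bool = False) -> Partition:
        removed_all: list[tuple[int, int]] = []
        try:
            return self._partition(thresholds, cutoff, per_node_split,
                                   removed_all)
        finally:
            amask = self.amask
            for u, v in removed_all:
                amask[u] |= 1 << v
                amask[v] |= 1 << u

    def _partition(self, thresholds: SeedThresholds, cutoff: float,
                   per_node_split: bool,
                   removed_all: list[tuple[int, int]]) -> Partition:
        clco, deg, amask = self.clco, self.deg, self.amask
        t1, t2 = thresholds.theta1, thresholds.theta2
        seeds = [k for k in self.ranked
                 if clco[k] >= cutoff
                 and not (cutoff < clco[k] < t2 and deg[k] > t1)]
        mem: list[Optional[int]] = []
        seedl: list[int] = []
        edg: list[int] = []
        seen: set[int] = set()
        for k in seeds:
            m = self.neigh_mask[k]
            if m in seen:
                continue
            seen.add(m)
            mem.append(m)
            seedl.append(k)
            edg.append(self.edges0[k])
        ncomm = len(mem)
        # static over-approximation of node -> containing communities;
        # memberships only shrink outside a community's own turn, so each
        # candidate hit is verified against the live masks below
        member_of: list[list[int]] = [[] for _ in range(self.n)]
        for idx in range(ncomm):
            k = seedl[idx]
            member_of[k].append(idx)
            for v in self.nbrs[k]:
                member_of[v].append(idx)

        i = 0
        cand: Optional[list[int]] = None  # min-heap of possible partners of i
        while i < ncomm:
            mi = mem[i]
            if mi is None:
                i += 1
                cand = None
                continue
            if cand is None:
                s: set[int] = set()
                for u in _bits(mi):
                    s.update(member_of[u])
                cand = [k for k in s if k > i]
                heapq.heapify(cand)
            j = None
            while cand:
                k = cand[0]
                mk = mem[k]
                if mk is None or not (mk & mi):
                    heapq.heappop(cand)  # dead or stale candidate
                    continue
                j = k
                break
            if j is None:
                i += 1
                cand = None
                continue

            a = mi
            b = mem[j]
            inter = a & b
            li = inter.bit_count()
            la, lb = a.bit_count(), b.bit_count()
            ea, eb = edg[i], edg[j]
            # E(A ∪ B) = E(base) + cross(D, base) + E(D), D the smaller side
            if lb <= la:
                diff = b & ~a
                base, e_base = a, ea
            else:
                diff = a & ~b
                base, e_base = b, eb
            e_union = e_base
            dd = 0
            for u in _bits(diff):
                au = amask[u]
                e_union += (au & base).bit_count()
                dd += (au & diff).bit_count()
            e_union += dd >> 1
            nu = la + lb - li
            if _set_clco_from(e_union, nu) >= cutoff:
                # merge into position i
                added = diff if lb <= la else b & ~a
                mem[i] = a | b
                edg[i] = e_union
                mem[j] = None
                fresh: set[int] = set()
                for u in _bits(added):
                    member_of[u].append(i)
                    fresh.update(member_of[u])
                for k in fresh:
                    if k > i and mem[k] is not None:
                        heapq.heappush(cand, k)
                continue

            rest_a = a & ~inter
            rest_b = b & ~inter
            ra_cnt = la - li
            rb_cnt = lb - li
            e_int = -1  # lazy

            if per_node_split:
                first_on_tie = seedl[i] <= seedl[j]
                to_first = 0
                to_second = 0
                for u in _bits(inter):
                    na = (amask[u] & rest_a).bit_count()
                    nb = (amask[u] & rest_b).bit_count()
                    if na > nb or (na == nb and first_on_tie):
                        to_first |= 1 << u
                    else:
                        to_second |= 1 << u
                new_a = rest_a | to_first
                new_b = rest_b | to_second
                removed: list[tuple[int, int]] = []
                for u in _bits(to_first):
                    for v in _bits(amask[u] & new_b):
                        removed.append((u, v))
                for u in _bits(to_second):
                    for v in _bits(amask[u] & rest_a):
                        removed.append((u, v))
                self._apply_removals(removed, removed_all, member_of,
                                     mem, edg, i, j)
                for idx, m in ((i, new_a), (j, new_b)):
                    if m:
                        e = 0
                        for u in _bits(m):
                            e += (amask[u] & m).bit_count()
                        mem[idx] = m
                        edg[idx] = e >> 1
                        if not (m >> seedl[idx]) & 1:
                            seedl[idx] = (m & -m).bit_length() - 1
                    else:
                        mem[idx] = None
                if mem[i] is None:
                    i += 1
                    cand = None
                continue

            # block split: count edges between the intersection and each rest
            if ra_cnt <= li:
                e1 = 0
                for u in _bits(rest_a):
                    e1 += (amask[u] & inter).bit_count()
            else:
                e_int = self._edges_within(inter)
                e1 = -2 * e_int
                for u in _bits(inter):
                    e1 += (amask[u] & a).bit_count()
            if rb_cnt <= li:
                e2 = 0
                for u in _bits(rest_b):
                    e2 += (amask[u] & inter).bit_count()
            else:
                if e_int < 0:
                    e_int = self._edges_within(inter)
                e2 = -2 * e_int
                for u in _bits(inter):
                    e2 += (amask[u] & b).bit_count()
            if e1 != e2:
                winner_first = e1 > e2
            else:
                if e_int < 0:
                    e_int = self._edges_within(inter)
                d1 = (_set_clco_from(ea, la)
                      - _set_clco_from(ea - e_int - e1, ra_cnt))
                d2 = (_set_clco_from(eb, lb)
                      - _set_clco_from(eb - e_int - e2, rb_cnt))
                if d1 != d2:
                    winner_first = d1 > d2
                else:
                    winner_first = seedl[i] <= seedl[j]
            if winner_first:
                lose_idx, lose_rest, e_lose, lr_cnt = j, rest_b, eb, rb_cnt
            else:
                lose_idx, lose_rest, e_lose, lr_cnt = i, rest_a, ea, ra_cnt
            removed = []
            if li <= lr_cnt:
                for u in _bits(inter):
                    for v in _bits(amask[u] & lose_rest):
                        removed.append((u, v))
            else:
                for v in _bits(lose_rest):
                    for u in _bits(amask[v] & inter):
                        removed.append((u, v))
            self._apply_removals(removed, removed_all, member_of,
                                 mem, edg, i, j)
            if lose_rest:
                if lr_cnt <= li:
                    er = self._edges_within(lose_rest)
                else:
                    if e_int < 0:
                        e_int = self._edges_within(inter)
                    er = e_lose - e_int - len(removed)
                mem[lose_idx] = lose_rest
                edg[lose_idx] = er
                if not (lose_rest >> seedl[lose_idx]) & 1:
                    seedl[lose_idx] = (lose_rest & -lose_rest).bit_length() - 1
            else:
                mem[lose_idx] = None
            if mem[i] is None:
                i += 1
                cand = None

        finals = [x for x in range(ncomm) if mem[x] is not None]
        covered = 0
        for x in finals:
            covered |= mem[x]
        nodes = self.nodes
        communities = [frozenset(nodes[u] for u in _bits(mem[x]))
                       for x in finals]
        communities.extend(frozenset((nodes[u],))
                           for u in _bits(self.full & ~covered))
        communities.sort(key=min)
        # cut accounting on the ORIGINAL component: maintained working
        # counts, plus severed edges that later merges brought back inside
        comm_idx = [-1] * self.n
        for where, x in enumerate(finals):
            for u in _bits(mem[x]):
                comm_idx[u] = where
        intra = sum(edg[x] for x in finals)
        for u, v in removed_all:
            if comm_idx[u] == comm_idx[v] and comm_idx[u] >= 0:
                intra += 1
        return Partition(communities=tuple(communities),
                         cut_size=self.total_edges - intra, cutoff=cutoff)

    def _edges_within(self, m: int) -> int:
        amask = self.amask
        e = 0
        for u in _bits(m):
            e += (amask[u] & m).bit_count()
        return e >> 1

    def _apply_removals(self, removed: list[tuple[int, int]],
                        removed_all: list[tuple[int, int]],
                        member_of: list[list[int]],
                        mem: list[Optional[int]], edg: list[int],
                        i: int, j: int) -> None:
        amask = self.amask
        for u, v in removed:
            amask[u] &= ~(1 << v)
            amask[v] &= ~(1 << u)
        removed_all.extend(removed)
        # keep the internal-edge counts of bystander communities honest
        for u, v in removed:
            for k in member_of[u]:
                if k != i and k != j:
                    mk = mem[k]
                    if mk is not None and (mk >> u) & 1 and (mk >> v) & 1:
                        edg[k] -= 1


def generate_partition(component: nx.Graph, stats: Mapping[int, NodeStats],
                       thresholds: SeedThresholds, cutoff: float,
                       per_node_split: bool = False) -> Partition:
    """Build the partition of one connected component at one cutoff.

    Seeds are selected and their neighbourhood communities refined
    pairwise — always the best-ranked community against the next one it
    intersects — until all communities are disjoint.  Nodes covered by no
    community become singletons.  The cut size is the number of component
    edges left between different communities.
    """
    return _ComponentEngine(component, stats).partition(
        thresholds, cutoff, per_node_split)


def best_partition(component: nx.Graph, stats: Mapping[int, NodeStats],
                   thresholds: SeedThresholds, schedule: CutoffSchedule,
                   per_node_split: bool = False) -> Partition:
    """Sweep the cutoff schedule and keep the minimum-cut partition.

    Ties on the cut go to the partition generated by the largest cutoff
    (the more conservative communities).  An empty schedule — every ClCo
    rounded to zero — returns the whole component as one community.
    """
    if not schedule.values:
        return Partition(communities=(frozenset(component.nodes),),
                         cut_size=0, cutoff=None)
    engine = _ComponentEngine(component, stats)
    best: Optional[Partition] = None
    for cutoff in schedule.values:  # decreasing; '<' keeps the larger cutoff on ties
        part = engine.partition(thresholds, cutoff, per_node_split)
        if best is None or part.cut_size < best.cut_size:
            best = part
    return best


def _solve_component(graph: nx.Graph, comp: frozenset[int],
                     all_stats: Mapping[int, NodeStats],
                     global_thresholds: Optional[SeedThresholds],
                     config: ClusterConfig) -> list[frozenset[int]]:
    if len(comp) == 1:
        return [frozenset(comp)]
    sub = graph.subgraph(comp).copy()
    stats = {n: all_stats[n] for n in comp}
    thresholds = (global_thresholds if global_thresholds is not None
                  else seed_thresholds(stats))
    schedule = cutoff_schedule(stats, config.rounding, config.max_cutoffs)
    part = best_partition(sub, stats, thresholds, schedule,
                          config.per_node_split)
    return list(part.communities)


def cluster_graph(graph: nx.Graph | SimilarityGraph,
                  config: Optional[ClusterConfig] = None) -> ClusterAssignment:
    """Cluster a whole similarity graph into gene-level read communities.

    Optionally disconnects articulation points first, then runs the
    cutoff sweep independently on every connected component; the output
    is a partition of the full node set.  Deterministic for a given
    configuration, regardless of thread count.
    """
    if config is None:
        config = ClusterConfig()
    g0 = graph.graph if isinstance(graph, SimilarityGraph) else graph
    if config.preprocess:
        g, _pool = disconnect_articulation_points(g0)
    else:
        g = g0
    if g.number_of_nodes() == 0:
        return ClusterAssignment([])
    all_stats = node_stats(g, rounding=config.rounding)
    global_thresholds = (seed_thresholds(all_stats)
                         if config.percentile_scope == "global" else None)
    decomp = connected_components(g)

    def solve(comp: frozenset[int]) -> list[frozenset[int]]:
        return _solve_component(g, comp, all_stats, global_thresholds, config)

    if config.threads > 1:
        with ThreadPoolExecutor(max_workers=config.threads) as pool:
            results = list(pool.map(solve, decomp.components))
    else:
        results = [solve(c) for c in decomp.components]
    clusters: list[frozenset[int]] = []
    for r in results:
        clusters.extend(r)
    return ClusterAssignment(clusters).canonical()
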