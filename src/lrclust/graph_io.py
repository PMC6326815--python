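"""Input/output for similarity graphs and cluster files.

Two input dialects are supported: PAF overlap records as emitted by a
minimap-class overlapper, and a plain whitespace-separated edge list over
integer read indexes.  Output is a plain-text cluster file with one line
per cluster, each line holding the member read indexes.

The similarity graph itself is an undirected simple :class:`networkx.Graph`
whose nodes are non-negative integer read indexes; reads seen in a PAF file
are indexed by first appearance, and a name<->index table can be written as
a sidecar so cluster lines can be mapped back to the source FASTA records.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

__all__ = [
    "OverlapRecord",
    "SimilarityGraph",
    "ClusterAssignment",
    "PafParseError",
    "EdgeListParseError",
    "ClusterFileError",
    "parse_paf",
    "build_graph",
    "parse_edge_list",
    "write_clusters",
    "read_clusters",
    "write_name_table",
    "read_name_table",
]


class PafParseError(ValueError):
    """Raised for a malformed PAF line; the message names the line number."""


class EdgeListParseError(ValueError):
    """Raised for a malformed edge-list line; the message names the line number."""


class ClusterFileError(ValueError):
    """Raised when a cluster file violates the partition invariants."""


@dataclass(frozen=True)
class OverlapRecord:
    """One overlap between two reads (one PAF line).

    Only the fields the clustering pipeline consumes are parsed into
    typed attributes; any PAF columns past the 12 mandatory ones are
    retained opaquely in ``extra``.
    """

    query_name: str
    query_len: int
    query_start: int
    query_end: int
    strand: str
    target_name: str
    target_len: int
    target_start: int
    target_end: int
    residue_matches: int
    block_len: int
    mapq: int
    extra: tuple[str, ...] = ()


@dataclass
class SimilarityGraph:
    """Undirected simple graph of read similarity.

    ``graph`` has integer read indexes as nodes and one edge per detected
    overlap; ``name_to_index`` maps read identifiers to indexes in
    first-appearance order (the identity map for edge-list input).
    """

    graph: nx.Graph
    name_to_index: dict[str, int] = field(default_factory=dict)

    @property
    def index_to_name(self) -> dict[int, str]:
        return {i: n for n, i in self.name_to_index.items()}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SimilarityGraph):
            return NotImplemented
        return (
            set(self.graph.nodes) == set(other.graph.nodes)
            and {frozenset(e) for e in self.graph.edges}
            == {frozenset(e) for e in other.graph.edges}
            and self.name_to_index == other.name_to_index
        )


@dataclass
class ClusterAssignment:
    """A disjoint family of node-index sets (implicit cluster ids 0..L-1)."""

    clusters: list[frozenset[int]]

    def __post_init__(self) -> None:
        clusters = [frozenset(c) for c in self.clusters]
        seen: set[int] = set()
        for c in clusters:
            if seen & c:
                dup = sorted(seen & c)
                raise ClusterFileError(f"node(s) {dup} appear in more than one cluster")
            seen |= c
        self.clusters = clusters

    def canonical(self) -> "ClusterAssignment":
        """Clusters ordered by smallest member; idempotent."""
        return ClusterAssignment(sorted(self.clusters, key=min))

    def support(self) -> frozenset[int]:
        out: set[int] = set()
        for c in self.clusters:
            out |= c
        return frozenset(out)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ClusterAssignment):
            return NotImplemented
        return sorted(self.clusters, key=min) == sorted(other.clusters, key=min)

    def __len__(self) -> int:
        return len(self.clusters)


def parse_paf(path: str | os.PathLike, min_block_len: int = 0) -> list[OverlapRecord]:
    """Parse a PAF overlap file into records, in file order.

    Self-overlaps (query == target) are dropped, as are records whose
    alignment-block length falls below ``min_block_len``.  An empty file
    yields an empty list.  Malformed lines (fewer than 12 tab-separated
    columns, non-numeric numeric fields, or impossible values) raise
    :class:`PafParseError` naming the offending line.
    """
    records: list[OverlapRecord] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise PafParseError(
                    f"line {lineno}: expected >=12 tab-separated columns, got {len(cols)}"
                )
            try:
                rec = OverlapRecord(
                    query_name=cols[0],
                    query_len=int(cols[1]),
                    query_start=int(cols[2]),
                    query_end=int(cols[3]),
                    strand=cols[4],
                    target_name=cols[5],
                    target_len=int(cols[6]),
                    target_start=int(cols[7]),
                    target_end=int(cols[8]),
                    residue_matches=int(cols[9]),
                    block_len=int(cols[10]),
                    mapq=int(cols[11]),
                    extra=tuple(cols[12:]),
                )
            except ValueError as exc:
                raise PafParseError(f"line {lineno}: non-numeric field ({exc})") from exc
            if rec.query_len <= 0 or rec.target_len <= 0:
                raise PafParseError(f"line {lineno}: non-positive read length")
            if rec.residue_matches > rec.block_len:
                raise PafParseError(
                    f"line {lineno}: residue matches exceed alignment block length"
                )
            if rec.query_name == rec.target_name:
                continue
            if rec.block_len < min_block_len:
                continue
            records.append(rec)
    return records


def build_graph(records: Iterable[OverlapRecord]) -> SimilarityGraph:
    """Build the similarity graph from overlap records.

    One node per distinct read name (indexed by first appearance, query
    before target within a record); one edge per distinct unordered read
    pair.  Duplicate and reciprocal records collapse onto a single edge.
    """
    name_to_index: dict[str, int] = {}
    g = nx.Graph()

    def index_of(name: str) -> int:
        idx = name_to_index.get(name)
        if idx is None:
            idx = len(name_to_index)
            name_to_index[name] = idx
            g.add_node(idx)
        return idx

    for rec in records:
        qi = index_of(rec.query_name)
        ti = index_of(rec.target_name)
        if qi != ti:
            g.add_edge(qi, ti)
    return SimilarityGraph(graph=g, name_to_index=name_to_index)


def parse_edge_list(path: str | os.PathLike) -> SimilarityGraph:
    """Parse a whitespace-separated edge list over integer read indexes.

    Each non-comment line holds two integer node tokens; '#' starts a
    comment line.  Self-pairs are dropped; duplicate pairs collapse.
    The node ids are taken verbatim, so the name map is the identity.
    """
    g = nx.Graph()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            tokens = stripped.split()
            if len(tokens) != 2:
                raise EdgeListParseError(
                    f"line {lineno}: expected 2 node tokens, got {len(tokens)}"
                )
            try:
                u, v = int(tokens[0]), int(tokens[1])
            except ValueError as exc:
                raise EdgeListParseError(
                    f"line {lineno}: non-integer node token"
                ) from exc
            if u < 0 or v < 0:
                raise EdgeListParseError(f"line {lineno}: negative node index")
            if u == v:
                continue
            g.add_edge(u, v)
    name_to_index = {str(n): n for n in g.nodes}
    return SimilarityGraph(graph=g, name_to_index=name_to_index)


def write_clusters(assignment: ClusterAssignment, path: str | os.PathLike) -> None:
    """Write a cluster file: one line per cluster, member indexes ascending
    and space-separated, clusters ordered by smallest member (bit-exact
    canonical dialect, so equal assignments produce identical files)."""
    canon = assignment.canonical()
    with open(path, "w", encoding="utf-8") as fh:
        for cluster in canon.clusters:
            fh.write(" ".join(str(n) for n in sorted(cluster)))
            fh.write("\n")


def read_clusters(path: str | os.PathLike) -> ClusterAssignment:
    """Read a cluster file; inverse of :func:`write_clusters` up to
    canonical ordering.  Duplicate indexes across lines or non-integer
    tokens raise :class:`ClusterFileError`."""
    clusters: list[frozenset[int]] = []
    seen: set[int] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            try:
                members = [int(tok) for tok in stripped.split()]
            except ValueError as exc:
                raise ClusterFileError(
                    f"line {lineno}: non-integer cluster member"
                ) from exc
            dup = seen.intersection(members)
            if dup or len(set(members)) != len(members):
                bad = sorted(dup) or sorted(
                    m for m in members if members.count(m) > 1
                )
                raise ClusterFileError(
                    f"line {lineno}: node(s) {bad} assigned to more than one cluster"
                )
            seen.update(members)
            clusters.append(frozenset(members))
    return ClusterAssignment(clusters).canonical()


def write_name_table(name_to_index: dict[str, int], path: str | os.PathLike) -> None:
    """Write the read-name <-> index sidecar as two-column TSV (index, name),
    sorted by index."""
    with open(path, "w", encoding="utf-8") as fh:
        for name, idx in sorted(name_to_index.items(), key=lambda kv: kv[1]):
            fh.write(f"{idx}\t{name}\n")


def read_name_table(path: str | os.PathLike) -> dict[str, int]:
    name_to_index: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            idx, name = line.rstrip("\n").split("\t")
            name_to_index[name] = int(idx)
    return name_to_index
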