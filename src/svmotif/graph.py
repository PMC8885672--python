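"""Per-sample rearrangement graphs and Hamiltonian-cycle mining.

Each sample becomes an undirected simple graph: final breakpoint clusters
are the vertices (located at their density-peak coordinate) and deduplicated
junctions between distinct clusters are the edges.  The mined patterns are
closed simple cycles of 3-6 vertices in which every participating vertex has
degree exactly 2 ("Hamiltonian cycles" of the induced subgraph).  Mining is
a depth-first path extension from every start vertex followed by a reduce
step that collapses duplicate discoveries via a canonical edge-set key — so
the per-start searches can run independently and merge to the same result
as a serial pass.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .cluster import Cluster
from .model import Adjacency, BreakendRef

logger = logging.getLogger(__name__)

Edge = frozenset  # frozenset of 2 vertex ids


@dataclass
class SampleGraph:
    """Deduplicated undirected cluster graph of one sample."""

    sample_id: str
    graph: nx.Graph  # nodes carry 'chrom' and 'peak_pos'; edges carry 'adjacencies'

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def vertex_sort_key(self, v: str) -> tuple:
        data = self.graph.nodes[v]
        return (data.get("chrom", ""), data.get("peak_pos", 0.0), v)

    def sorted_vertices(self) -> list[str]:
        return sorted(self.graph.nodes, key=self.vertex_sort_key)


def build_sample_graph(
    sample_id: str,
    clusters: Sequence[Cluster],
    adjacencies: Sequence[Adjacency],
    assignment: Mapping[BreakendRef, str],
) -> SampleGraph:
    """Build the deduplicated cluster graph of one sample.

    One edge per distinct cluster pair regardless of how many junctions
    connect them; junctions whose two ends fall in the same cluster are
    dropped with a logged count (the loop filter should already have removed
    them).  Edge provenance keeps the contributing adjacency ids.
    """
    g = nx.Graph()
    for c in clusters:
        if c.sample_id == sample_id:
            g.add_node(c.id, chrom=c.chrom, peak_pos=c.peak_pos)
    n_loops = 0
    for adj in adjacencies:
        if adj.sample_id != sample_id:
            continue
        try:
            u = assignment[(adj.id, 0)]
            v = assignment[(adj.id, 1)]
        except KeyError as exc:
            raise ValueError(f"breakend {exc} not assigned to a final cluster")
        if u == v:
            n_loops += 1
            continue
        if g.has_edge(u, v):
            g.edges[u, v]["adjacencies"].append(adj.id)
        else:
            g.add_edge(u, v, adjacencies=[adj.id])
    if n_loops:
        logger.info("sample %s: dropped %d self-loop junctions", sample_id, n_loops)
    for _u, _v, data in g.edges(data=True):
        data["adjacencies"].sort()
    return SampleGraph(sample_id=sample_id, graph=g)


def canonical_cycle_key(edge_set: Iterable[tuple[str, str] | frozenset]) -> str:
    """Canonical key of a simple cycle given as an edge set.

    The key depends only on the set of undirected edges, so it is invariant
    to rotation/reflection of the cycle and to edge ordering.  Non-cycle
    inputs (any vertex degree != 2, or a disconnected 2-regular graph) raise.
    """
    edges = [tuple(sorted(e)) for e in edge_set]
    if len(set(edges)) != len(edges):
        raise ValueError("duplicate edges in cycle edge set")
    degree: dict[str, int] = {}
    neighbors: dict[str, list[str]] = {}
    for u, v in edges:
        if u == v:
            raise ValueError("self-loop in cycle edge set")
        degree[u] = degree.get(u, 0) + 1
        degree[v] = degree.get(v, 0) + 1
        neighbors.setdefault(u, []).append(v)
        neighbors.setdefault(v, []).append(u)
    if any(d != 2 for d in degree.values()) or len(degree) != len(edges):
        raise ValueError("edge set is not a single simple cycle")
    # connectivity: walk the cycle from an arbitrary vertex
    start = next(iter(neighbors))
    seen = {start}
    prev, cur = None, start
    for _ in range(len(edges)):
        nxt = [w for w in neighbors[cur] if w != prev]
        prev, cur = cur, nxt[0] if nxt else neighbors[cur][0]
        seen.add(cur)
    if len(seen) != len(degree):
        raise ValueError("edge set is not a single simple cycle")
    return ";".join(f"{u}|{v}" for u, v in sorted(edges))


@dataclass(frozen=True)
class CycleOccurrence:
    """One simple closed cycle of k distinct clusters in one sample."""

    sample_id: str
    size: int
    edge_set: frozenset  # frozenset of frozenset({u, v})
    canonical_key: str
    vertices: tuple[str, ...]  # one cyclic order, for reporting

    def __post_init__(self) -> None:
        if not 3 <= self.size <= 6:
            raise ValueError(f"cycle size {self.size} outside [3, 6]")


def _cycle_from_path(sample_id: str, path: list[str]) -> CycleOccurrence:
    edges = frozenset(
        frozenset((path[i], path[(i + 1) % len(path)])) for i in range(len(path))
    )
    return CycleOccurrence(
        sample_id=sample_id,
        size=len(path),
        edge_set=edges,
        canonical_key=canonical_cycle_key(edges),
        vertices=tuple(path),
    )


def enumerate_cycles(
    sg: SampleGraph,
    k_min: int = 3,
    k_max: int = 6,
    start_vertices: Sequence[str] | None = None,
) -> list[CycleOccurrence]:
    """Depth-first enumeration of simple cycles with k_min <= k <= k_max vertices.

    Paths are grown from every start vertex and closed whenever the last
    vertex neighbours the first; duplicate discoveries (each cycle is found
    once per traversal direction and start vertex) are reduced via the
    canonical key.  Restricting *start_vertices* yields exactly the cycles
    through those vertices, so a partitioned search merged over all starts
    equals the serial result.
    """
    g = sg.graph
    adjacency = {v: sorted(g.neighbors(v), key=sg.vertex_sort_key) for v in g.nodes}
    found: dict[str, CycleOccurrence] = {}
    starts = list(start_vertices) if start_vertices is not None else sg.sorted_vertices()

    def extend(path: list[str], on_path: set[str]) -> None:
        last = path[-1]
        if len(path) >= k_min and path[0] in adjacency[last] and len(path) > 2:
            occ = _cycle_from_path(sg.sample_id, path)
            found.setdefault(occ.canonical_key, occ)
        if len(path) == k_max:
            return
        for nxt in adjacency[last]:
            if nxt not in on_path:
                path.append(nxt)
                on_path.add(nxt)
                extend(path, on_path)
                on_path.remove(nxt)
                path.pop()

    for start in starts:
        extend([start], {start})
    return sorted(found.values(), key=lambda o: (o.size, o.canonical_key))


def mine_dataset(
    graphs: Iterable[SampleGraph], k_min: int = 3, k_max: int = 6
) -> list[CycleOccurrence]:
    """Mine every sample graph; occurrences are deduplicated per sample."""
    occurrences: list[CycleOccurrence] = []
    for sg in graphs:
        occurrences.extend(enumerate_cycles(sg, k_min=k_min, k_max=k_max))
    return occurrences


@dataclass
class PatternStats:
    """Cohort statistics for one cycle size.

    confidence: number of samples with at least one occurrence;
    frequency: total occurrences across the dataset;
    average: frequency / confidence.
    """

    pattern: int
    confidence: int
    frequency: int
    average: float
    degenerate: bool = False  # confidence == 0


def pattern_average(frequency: float, confidence: float) -> float:
    """Occurrences per occurrence-bearing sample (frequency / confidence)."""
    if confidence == 0:
        return 0.0
    return frequency / confidence


def truncate2(value: float) -> float:
    """Truncate toward zero at 2 decimals (the reporting convention for averages)."""
    return math.trunc(value * 100) / 100


def pattern_statistics(
    occurrences: Sequence[CycleOccurrence],
    all_sample_ids: Sequence[str],
    sizes: Sequence[int] = (3, 4, 5, 6),
) -> list[PatternStats]:
    n_samples = len(set(all_sample_ids))
    stats: list[PatternStats] = []
    for size in sizes:
        of_size = [o for o in occurrences if o.size == size]
        samples = {o.sample_id for o in of_size}
        confidence = len(samples)
        if confidence > n_samples:
            raise ValueError("more occurrence-bearing samples than samples")
        frequency = len(of_size)
        stats.append(
            PatternStats(
                pattern=size,
                confidence=confidence,
                frequency=frequency,
                average=pattern_average(frequency, confidence),
                degenerate=confidence == 0,
            )
        )
    return stats


def pattern_statistics_frame(stats: Sequence[PatternStats]) -> pd.DataFrame:
    """Cohort statistics table (average also truncated to 2 dp for display)."""
    return pd.DataFrame(
        [
            {
                "cycle_size": s.pattern,
                "confidence": s.confidence,
                "average": truncate2(s.average),
                "frequency": s.frequency,
            }
            for s in stats
        ]
    )


def occurrences_to_records(
    occurrences: Sequence[CycleOccurrence], graphs: Mapping[str, SampleGraph]
) -> list[dict]:
    """JSON-ready records (sample, size, vertices with coordinates, key)."""
    records = []
    for o in occurrences:
        nodes = graphs[o.sample_id].graph.nodes if o.sample_id in graphs else {}
        records.append(
            {
                "sample": o.sample_id,
                "size": o.size,
                "canonical_key": o.canonical_key,
                "vertices": [
                    {
                        "cluster_id": v,
                        "chrom": nodes[v].get("chrom") if v in nodes else None,
                        "peak_pos": nodes[v].get("peak_pos") if v in nodes else None,
                    }
                    for v in o.vertices
                ],
            }
        )
    return records
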