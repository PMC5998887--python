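"""Delta-team discovery on weighted undirected graphs over a shared vertex set.

A *delta-set* of a graph is a vertex set in which every pair of members is
linked by a chain of members whose consecutive shortest-path distances are at
most ``delta``; chains may route through vertices outside the set (only the
chain's *members* are constrained, paths between consecutive members are
unrestricted).  A *delta-cluster* of ``k >= 2`` graphs is a subset of their
shared vertex set that is a delta-set in every graph; a *delta-team* is a
maximal delta-cluster.  Teams partition the shared vertex set.

Teams are computed with a divide-and-conquer decomposition: an
early-terminating simultaneous traversal (:func:`smallmax`) either certifies
that the current working set is a delta-set in every graph (then it is a
team) or produces a proper maximal delta-subset in one graph, which splits
the working set into two independent halves.

An alternative *threshold-graph* mode replaces every input graph by a unit
graph connecting vertices at shortest-path distance at most ``delta`` and
then finds 1-teams; both modes return identical partitions.
"""

from __future__ import annotations

import heapq
import logging
import math
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Iterator, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

Vertex = Hashable

INF = math.inf


class GraphInputError(ValueError):
    """Invalid graph data supplied by the caller (unknown vertex, empty query...)."""


def _vkey(v: Vertex) -> str:
    """Deterministic total order on opaque vertex identifiers."""
    return str(v)


class WeightedGraph:
    """Undirected graph with non-negative edge weights.

    Parallel edges collapse to the minimum weight, self-loops are dropped
    with a warning.  The induced distance is the weighted shortest path
    (``inf`` when no path exists).
    """

    __slots__ = ("name", "_adj")

    def __init__(self, name: str | None = None):
        self.name = name
        self._adj: dict[Vertex, dict[Vertex, float]] = {}

    # -- construction -----------------------------------------------------

    def add_vertex(self, v: Vertex) -> None:
        self._adj.setdefault(v, {})

    def add_edge(self, u: Vertex, v: Vertex, weight: float) -> None:
        w = float(weight)
        if w < 0 or math.isnan(w):
            raise GraphInputError(f"edge ({u!r}, {v!r}) has invalid weight {weight!r}")
        if u == v:
            logger.warning("dropping self-loop on vertex %r", u)
            self.add_vertex(u)
            return
        self.add_vertex(u)
        self.add_vertex(v)
        old = self._adj[u].get(v)
        if old is None or w < old:
            self._adj[u][v] = w
            self._adj[v][u] = w

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[Vertex, Vertex, float]],
        vertices: Iterable[Vertex] = (),
        name: str | None = None,
    ) -> "WeightedGraph":
        g = cls(name=name)
        for v in vertices:
            g.add_vertex(v)
        for u, v, w in edges:
            g.add_edge(u, v, w)
        return g

    # -- queries ----------------------------------------------------------

    @property
    def vertices(self) -> frozenset:
        return frozenset(self._adj)

    def __contains__(self, v: Vertex) -> bool:
        return v in self._adj

    def __len__(self) -> int:
        return len(self._adj)

    def neighbors(self, v: Vertex) -> Mapping[Vertex, float]:
        try:
            return self._adj[v]
        except KeyError:
            raise GraphInputError(f"unknown vertex {v!r}") from None

    def edges(self) -> Iterator[tuple[Vertex, Vertex, float]]:
        seen = set()
        for u, nbrs in self._adj.items():
            for v, w in nbrs.items():
                key = (u, v) if _vkey(u) <= _vkey(v) else (v, u)
                if key not in seen:
                    seen.add(key)
                    yield key[0], key[1], w

    def weight(self, u: Vertex, v: Vertex) -> float | None:
        """Weight of edge (u, v), or None when absent.  Symmetric."""
        if u not in self._adj:
            raise GraphInputError(f"unknown vertex {u!r}")
        if v not in self._adj:
            raise GraphInputError(f"unknown vertex {v!r}")
        return self._adj[u].get(v)

    def pruned(self, delta: float) -> "WeightedGraph":
        """Copy without edges heavier than ``delta``.

        A single edge heavier than ``delta`` cannot lie on any path of total
        length <= ``delta`` (weights are non-negative), so pruning never
        changes the teams at that threshold.
        """
        g = WeightedGraph(name=self.name)
        for v in self._adj:
            g.add_vertex(v)
        for u, v, w in self.edges():
            if w <= delta:
                g.add_edge(u, v, w)
        return g


def shortest_path_distance(graph: WeightedGraph, u: Vertex, v: Vertex) -> float:
    """Length of the shortest u-v path (sum of edge weights); inf if none."""
    if u not in graph:
        raise GraphInputError(f"unknown vertex {u!r}")
    if v not in graph:
        raise GraphInputError(f"unknown vertex {v!r}")
    if u == v:
        return 0.0
    dist = {u: 0.0}
    heap: list[tuple[float, str, Vertex]] = [(0.0, _vkey(u), u)]
    while heap:
        d, _, x = heapq.heappop(heap)
        if d > dist.get(x, INF):
            continue
        if x == v:
            return d
        for y, w in graph.neighbors(x).items():
            nd = d + w
            if nd < dist.get(y, INF):
                dist[y] = nd
                heapq.heappush(heap, (nd, _vkey(y), y))
    return INF


def single_source_distances(graph: WeightedGraph, source: Vertex) -> dict:
    """Dijkstra distances from ``source`` to every reachable vertex."""
    if source not in graph:
        raise GraphInputError(f"unknown vertex {source!r}")
    dist = {source: 0.0}
    heap: list[tuple[float, str, Vertex]] = [(0.0, _vkey(source), source)]
    while heap:
        d, _, x = heapq.heappop(heap)
        if d > dist.get(x, INF):
            continue
        for y, w in graph.neighbors(x).items():
            nd = d + w
            if nd < dist.get(y, INF):
                dist[y] = nd
                heapq.heappush(heap, (nd, _vkey(y), y))
    return dist


def bounded_expand(
    graph: WeightedGraph,
    members: frozenset | set,
    visited: frozenset | set,
    delta: float,
) -> Vertex | None:
    """Next member reachable within ``delta`` of the visited set, or None.

    Returns some ``s`` in ``members - visited`` with
    ``min(d(s, t) for t in visited) <= delta``.  Traversal may pass through
    vertices outside ``members`` — only endpoints must be members.  Among
    equally near candidates the smallest id is returned (determinism).
    """
    if not visited:
        raise ValueError("bounded_expand requires a non-empty visited set")
    if not set(visited) <= set(members):
        raise ValueError("visited must be a subset of members")
    dist: dict[Vertex, float] = {}
    heap: list[tuple[float, str, Vertex]] = []
    for t in visited:
        if t not in graph:
            raise GraphInputError(f"unknown vertex {t!r}")
        dist[t] = 0.0
        heapq.heappush(heap, (0.0, _vkey(t), t))
    members = set(members)
    visited = set(visited)
    while heap:
        d, _, x = heapq.heappop(heap)
        if d > dist.get(x, INF) or d > delta:
            continue
        if x in members and x not in visited:
            return x
        for y, w in graph.neighbors(x).items():
            nd = d + w
            if nd <= delta and nd < dist.get(y, INF):
                dist[y] = nd
                heapq.heappush(heap, (nd, _vkey(y), y))
    return None


class _Traversal:
    """Incremental single-linkage closure of one member set in one graph.

    Maintains a truncated multi-source Dijkstra whose source set grows as
    members are absorbed: every absorbed member restarts at distance 0, so a
    vertex's tentative distance is its distance to the nearest absorbed
    member.  ``step`` yields one newly reachable member per call, or None
    once no unvisited member lies within ``delta`` of the visited set.
    """

    __slots__ = ("graph", "members", "delta", "visited", "dist", "heap", "exhausted")

    def __init__(self, graph: WeightedGraph, members: frozenset, delta: float, start: Vertex):
        self.graph = graph
        self.members = members
        self.delta = delta
        self.visited = {start}
        self.dist = {start: 0.0}
        self.heap: list[tuple[float, str, Vertex]] = [(0.0, _vkey(start), start)]
        self.exhausted = False

    def step(self) -> Vertex | None:
        if self.exhausted:
            return None
        delta = self.delta
        while self.heap:
            d, _, x = heapq.heappop(self.heap)
            if d > self.dist.get(x, INF) or d > delta:
                continue
            if x in self.members and x not in self.visited:
                # absorb: x becomes a source of the closure
                self.visited.add(x)
                self.dist[x] = 0.0
                heapq.heappush(self.heap, (0.0, _vkey(x), x))
                return x
            for y, w in self.graph.neighbors(x).items():
                nd = d + w
                if nd <= delta and nd < self.dist.get(y, INF):
                    self.dist[y] = nd
                    heapq.heappush(self.heap, (nd, _vkey(y), y))
        self.exhausted = True
        return None


@dataclass(frozen=True)
class TeamQuery:
    """A team-finding problem: k >= 2 graphs and a distance threshold."""

    graphs: tuple[WeightedGraph, ...]
    delta: float
    shared_vertices: frozenset = field(init=False)

    def __post_init__(self):
        if len(self.graphs) < 2:
            raise GraphInputError("a team query needs at least two graphs")
        if self.delta < 0:
            raise GraphInputError(f"delta must be >= 0, got {self.delta}")
        shared = frozenset.intersection(*(g.vertices for g in self.graphs))
        if not shared:
            raise GraphInputError("the graphs share no vertices")
        object.__setattr__(self, "shared_vertices", shared)


@dataclass(frozen=True)
class TeamPartition:
    """All delta-teams of a query; they partition the shared vertex set."""

    teams: tuple[tuple[Vertex, ...], ...]
    delta: float

    def as_sets(self) -> list[frozenset]:
        return [frozenset(t) for t in self.teams]


def _smallmax(
    graphs: Sequence[WeightedGraph],
    delta: float,
    member_sets: Sequence[frozenset],
) -> tuple[int, frozenset]:
    """Find a maximal delta-set inside one of the member sets.

    Expansion steps alternate round-robin across the graphs (one step per
    graph per loop iteration, in input order) so the search terminates as
    early as possible: the first graph whose traversal exhausts on a proper
    subset of its member set wins and that subset is returned.  Only when
    every member set is a delta-set in its own graph is the full set
    returned, by convention with the index of the last graph.
    """
    k = len(graphs)
    for s in member_sets:
        if not s:
            raise ValueError("smallmax requires non-empty member sets")
    travs = [
        _Traversal(graphs[i], frozenset(member_sets[i]), delta, min(member_sets[i], key=_vkey))
        for i in range(k)
    ]
    finished = [False] * k
    while not all(finished):
        for i in range(k):
            if finished[i]:
                continue
            s = travs[i].step()
            if s is None:
                if len(travs[i].visited) < len(member_sets[i]):
                    return i, frozenset(travs[i].visited)
                finished[i] = True
    return k - 1, frozenset(member_sets[k - 1])


def smallmax(query: TeamQuery, member_sets: Sequence[frozenset]) -> tuple[int, frozenset]:
    """Public wrapper of the simultaneous bounded traversal (see module doc)."""
    return _smallmax(query.graphs, query.delta, member_sets)


def decompose(query: TeamQuery, working_set: frozenset, accumulator: list) -> None:
    """Append to ``accumulator`` all delta-teams contained in ``working_set``.

    Whenever the traversal certifies a proper maximal delta-subset ``S'`` of
    the working set in one graph, the teams of the working set are exactly
    the teams of ``S'`` plus the teams of the remainder, so both halves are
    processed independently.
    """
    if not working_set:
        raise ValueError("decompose requires a non-empty working set")
    stack = [frozenset(working_set)]
    while stack:
        s = stack.pop()
        if len(s) == 1:
            accumulator.append(s)
            continue
        _, sub = _smallmax(query.graphs, query.delta, [s] * len(query.graphs))
        if sub == s:
            accumulator.append(s)
        else:
            stack.append(s - sub)
            stack.append(sub)


def _canonical_partition(teams: Iterable[frozenset], delta: float) -> TeamPartition:
    ordered = sorted(
        (tuple(sorted(t, key=_vkey)) for t in teams),
        key=lambda t: [_vkey(v) for v in t],
    )
    return TeamPartition(teams=tuple(ordered), delta=delta)


def find_delta_teams(graphs: Sequence[WeightedGraph], delta: float) -> TeamPartition:
    """All delta-teams over the shared vertex set, canonically ordered."""
    query = TeamQuery(graphs=tuple(graphs), delta=float(delta))
    acc: list[frozenset] = []
    decompose(query, query.shared_vertices, acc)
    return _canonical_partition(acc, float(delta))


# -- threshold-graph mode -------------------------------------------------


def all_pairs_distances(graph: WeightedGraph) -> tuple[list, np.ndarray]:
    """All-pairs shortest-path matrix (Floyd-Warshall), plus vertex order."""
    from scipy.sparse.csgraph import csgraph_from_dense, floyd_warshall

    verts = sorted(graph.vertices, key=_vkey)
    n = len(verts)
    idx = {v: i for i, v in enumerate(verts)}
    dense = np.full((n, n), np.inf)
    for u, v, w in graph.edges():
        i, j = idx[u], idx[v]
        if w < dense[i, j]:
            dense[i, j] = w
            dense[j, i] = w
    sparse = csgraph_from_dense(dense, null_value=np.inf)
    dist = floyd_warshall(sparse, directed=False)
    np.fill_diagonal(dist, 0.0)
    return verts, dist


def build_threshold_graph(
    graph: WeightedGraph, candidate_vertices: Iterable[Vertex], delta: float
) -> WeightedGraph:
    """Unit graph on the candidates, edges where shortest-path distance <= delta."""
    cands = sorted(set(candidate_vertices), key=_vkey)
    for v in cands:
        if v not in graph:
            raise GraphInputError(f"unknown vertex {v!r}")
    verts, dist = all_pairs_distances(graph)
    idx = {v: i for i, v in enumerate(verts)}
    tg = WeightedGraph(name=graph.name)
    for v in cands:
        tg.add_vertex(v)
    for a in range(len(cands)):
        ia = idx[cands[a]]
        for b in range(a + 1, len(cands)):
            if dist[ia, idx[cands[b]]] <= delta:
                tg.add_edge(cands[a], cands[b], 1.0)
    return tg


def find_teams_via_threshold(graphs: Sequence[WeightedGraph], delta: float) -> TeamPartition:
    """Same result as :func:`find_delta_teams`, via the threshold-graph route."""
    if len(graphs) < 2:
        raise GraphInputError("a team query needs at least two graphs")
    if delta < 0:
        raise GraphInputError(f"delta must be >= 0, got {delta}")
    shared = frozenset.intersection(*(g.vertices for g in graphs))
    if not shared:
        raise GraphInputError("the graphs share no vertices")
    thresholded = [build_threshold_graph(g, shared, delta) for g in graphs]
    part = find_delta_teams(thresholded, 1.0)
    return TeamPartition(teams=part.teams, delta=float(delta))
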