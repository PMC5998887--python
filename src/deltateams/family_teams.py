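"""Delta-team discovery when vertices carry family labels.

Correspondence between graphs is by family rather than vertex identity: a
team is a tuple of per-graph vertex sets with identical family spectra, each
a delta-set in its own graph, maximal component-wise.  Unlike the
shared-vertex case teams may overlap (the same family can occur in several
teams), so no partition property holds.

The decomposition splits on a proper maximal delta-set ``B`` found in one
graph: the teams of the instance are the teams of the ``B``-branch (every
other graph restricted to the families of ``B``) plus the teams of the
remainder branch (restricted to the families of the remainder).  The two
branches may overlap in the other graphs' vertices, hence outputs are
deduplicated, and a final component-wise dominance filter enforces
maximality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping, Sequence

from .graph_core import (
    GraphInputError,
    Vertex,
    WeightedGraph,
    _smallmax,
    _vkey,
)

logger = logging.getLogger(__name__)

Family = Hashable


@dataclass(frozen=True)
class FamilyGraph:
    """A weighted graph whose vertices carry (exactly one) family label each."""

    graph: WeightedGraph
    family_of: Mapping[Vertex, Family]

    def __post_init__(self):
        missing = [v for v in self.graph.vertices if v not in self.family_of]
        if missing:
            raise GraphInputError(
                f"vertices without family label: {sorted(map(str, missing))[:5]}"
            )

    @property
    def families(self) -> frozenset:
        return frozenset(self.family_of[v] for v in self.graph.vertices)

    @property
    def vertices(self) -> frozenset:
        return self.graph.vertices


class FamilyIndex:
    """Per-graph tables mapping family identifiers to their member vertices."""

    def __init__(self, graphs: Sequence[FamilyGraph]):
        self._members: list[dict[Family, tuple[Vertex, ...]]] = []
        self._family_of: list[Mapping[Vertex, Family]] = []
        for fg in graphs:
            table: dict[Family, list[Vertex]] = {}
            for v in sorted(fg.graph.vertices, key=_vkey):
                table.setdefault(fg.family_of[v], []).append(v)
            self._members.append({f: tuple(vs) for f, vs in table.items()})
            self._family_of.append(fg.family_of)

    def members(self, graph_id: int, family: Family) -> tuple[Vertex, ...]:
        return self._members[graph_id].get(family, ())

    def family(self, graph_id: int, vertex: Vertex) -> Family:
        return self._family_of[graph_id][vertex]


def family_spectrum(graph: FamilyGraph, vertices: Iterable[Vertex]) -> frozenset:
    """Set of distinct family labels of the given vertices."""
    out = set()
    for v in vertices:
        if v not in graph.graph:
            raise GraphInputError(f"unknown vertex {v!r}")
        out.add(graph.family_of[v])
    return frozenset(out)


def restrict_by_families(
    index: FamilyIndex,
    graph_id: int,
    member_set: Iterable[Vertex],
    spectrum: frozenset,
) -> frozenset:
    """Members whose family lies in ``spectrum``; O(|member_set|)."""
    return frozenset(v for v in member_set if index.family(graph_id, v) in spectrum)


@dataclass(frozen=True)
class FamilyTeam:
    """One vertex set per graph, equal family spectra, maximal delta-cluster."""

    vertex_sets: tuple[frozenset, ...]
    family_spectrum: frozenset
    delta: float

    @property
    def size(self) -> int:
        """Team size: the largest per-graph member count."""
        return max(len(s) for s in self.vertex_sets)

    def canonical(self) -> tuple[tuple[Vertex, ...], ...]:
        return tuple(tuple(sorted(s, key=_vkey)) for s in self.vertex_sets)


def decompose_families(
    graphs: Sequence[FamilyGraph],
    member_sets: Sequence[frozenset],
    delta: float,
    accumulator: list,
    index: FamilyIndex | None = None,
) -> None:
    """Append all family delta-teams contained component-wise in the member sets.

    Raw output may contain duplicates and dominated clusters (the two
    branches of the split overlap); callers normally go through
    :func:`find_delta_teams_families`, which cleans up.
    """
    if index is None:
        index = FamilyIndex(graphs)
    k = len(graphs)
    spectra = [
        frozenset(index.family(i, v) for v in member_sets[i]) for i in range(k)
    ]
    if len(set(spectra)) != 1:
        raise ValueError("member sets must have equal family spectra on entry")
    raw = [_smallmax([fg.graph for fg in graphs], delta, member_sets)]
    stack: list[tuple[tuple[frozenset, ...], tuple[int, frozenset]]] = [
        (tuple(frozenset(s) for s in member_sets), raw[0])
    ]
    while stack:
        sets, (gi, sub) = stack.pop()
        if sub == sets[gi] and all(len(s) > 0 for s in sets):
            # smallmax returned a full member set: every set is a delta-set
            accumulator.append(sets)
            continue
        spectrum_b = frozenset(index.family(gi, v) for v in sub)
        remainder = sets[gi] - sub
        spectrum_r = frozenset(index.family(gi, v) for v in remainder)
        branch_b = tuple(
            sub if i == gi else restrict_by_families(index, i, sets[i], spectrum_b)
            for i in range(k)
        )
        branch_r = tuple(
            remainder if i == gi else restrict_by_families(index, i, sets[i], spectrum_r)
            for i in range(k)
        )
        # remainder branch pushed first so the B-branch is explored first
        stack.append((branch_r, _smallmax([fg.graph for fg in graphs], delta, branch_r)))
        stack.append((branch_b, _smallmax([fg.graph for fg in graphs], delta, branch_b)))


def _dominated(a: tuple[frozenset, ...], b: tuple[frozenset, ...]) -> bool:
    """True when ``a`` is component-wise contained in a different tuple ``b``."""
    return a != b and all(sa <= sb for sa, sb in zip(a, b))


def find_delta_teams_families(
    graphs: Sequence[FamilyGraph], delta: float
) -> list[FamilyTeam]:
    """All maximal delta-clusters with families, canonically ordered.

    Vertices whose family is absent from some graph are removed from the
    member sets up front (they still serve as path intermediates in the
    underlying graphs).
    """
    if len(graphs) < 2:
        raise GraphInputError("need at least two family graphs")
    if delta < 0:
        raise GraphInputError(f"delta must be >= 0, got {delta}")
    common = frozenset.intersection(*(fg.families for fg in graphs))
    if not common:
        raise GraphInputError("the graphs share no families")
    member_sets = []
    for i, fg in enumerate(graphs):
        kept = frozenset(v for v in fg.vertices if fg.family_of[v] in common)
        dropped = len(fg.vertices) - len(kept)
        if dropped:
            logger.info(
                "graph %d: dropped %d vertices of families absent elsewhere", i, dropped
            )
        member_sets.append(kept)
    index = FamilyIndex(graphs)
    acc: list[tuple[frozenset, ...]] = []
    decompose_families(graphs, member_sets, float(delta), acc, index=index)
    # dedupe, then discard component-wise dominated clusters
    unique = {tuple(tuple(sorted(s, key=_vkey)) for s in t): t for t in acc}
    tuples = list(unique.values())
    maximal = [t for t in tuples if not any(_dominated(t, o) for o in tuples)]
    teams = [
        FamilyTeam(
            vertex_sets=t,
            family_spectrum=frozenset(index.family(0, v) for v in t[0]),
            delta=float(delta),
        )
        for t in maximal
    ]
    teams.sort(key=lambda tm: [[_vkey(v) for v in s] for s in tm.canonical()])
    return teams
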