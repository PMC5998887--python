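"""Brute-force reference implementations and seeded synthetic-data generators.

The oracle for the shared-vertex case is alternating per-graph component
refinement: starting from the whole shared vertex set, each part is
repeatedly replaced by the connected components of its per-graph threshold
graph (full-graph shortest-path distances <= delta) until stable.  This
matches the chain-based definition exactly; thresholding the pointwise-max
distance matrix does NOT (per-graph chains may differ — see
``tests/test_synth_oracle.py`` for the permanent counterexample).

The family oracle enumerates all family-consistent subset tuples on tiny
instances and keeps the component-wise maximal ones.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

import networkx as nx
import numpy as np

from .family_teams import FamilyGraph, FamilyTeam, _dominated
from .graph_core import (
    TeamPartition,
    Vertex,
    WeightedGraph,
    _canonical_partition,
    _vkey,
    single_source_distances,
)
from .hic_graphs import Gene, GenomeAnnotation, HiCMap
from .go_scoring import GoAnnotations, GoDag


# -- reference checks ------------------------------------------------------


def check_delta_set(graph: WeightedGraph, vertices: Iterable[Vertex], delta: float) -> bool:
    """True iff the threshold graph on the set (full-graph shortest-path
    distance <= delta between members) is connected — the chain condition."""
    vs = sorted(set(vertices), key=_vkey)
    if len(vs) <= 1:
        return True
    tg = nx.Graph()
    tg.add_nodes_from(vs)
    for v in vs:
        dist = single_source_distances(graph, v)
        for u in vs:
            if u != v and dist.get(u, math.inf) <= delta:
                tg.add_edge(v, u)
    return nx.is_connected(tg)


def _threshold_components(
    distances: dict, part: frozenset, delta: float
) -> list[frozenset]:
    tg = nx.Graph()
    tg.add_nodes_from(part)
    for v in part:
        dv = distances[v]
        for u in part:
            if u != v and dv.get(u, math.inf) <= delta:
                tg.add_edge(v, u)
    return [frozenset(c) for c in nx.connected_components(tg)]


def oracle_teams(graphs: Sequence[WeightedGraph], delta: float) -> TeamPartition:
    """Fixpoint of alternating per-graph component refinement (small instances)."""
    shared = frozenset.intersection(*(g.vertices for g in graphs))
    if not shared:
        raise ValueError("the graphs share no vertices")
    distances = [
        {v: single_source_distances(g, v) for v in shared} for g in graphs
    ]
    parts = [shared]
    changed = True
    while changed:
        changed = False
        for dist in distances:
            new_parts = []
            for part in parts:
                comps = _threshold_components(dist, part, delta)
                if len(comps) > 1:
                    changed = True
                new_parts.extend(comps)
            parts = new_parts
    return _canonical_partition(parts, float(delta))


def oracle_family_teams(
    family_graphs: Sequence[FamilyGraph], delta: float, max_vertices: int = 6
) -> list[FamilyTeam]:
    """Exhaustive enumeration of maximal family delta-clusters (tiny instances).

    Enumerates every tuple of non-empty per-graph delta-set subsets with
    equal family spectra and retains the component-wise maximal tuples.
    """
    common = frozenset.intersection(*(fg.families for fg in family_graphs))
    if not common:
        raise ValueError("the graphs share no families")
    kept_sets = []
    for fg in family_graphs:
        kept = sorted(
            (v for v in fg.vertices if fg.family_of[v] in common), key=_vkey
        )
        if len(kept) > max_vertices:
            raise ValueError(
                f"instance too large for exhaustive enumeration ({len(kept)} > {max_vertices})"
            )
        kept_sets.append(kept)
    # per graph: delta-set subsets grouped by spectrum
    by_spectrum: list[dict[frozenset, list[frozenset]]] = []
    for fg, kept in zip(family_graphs, kept_sets):
        table: dict[frozenset, list[frozenset]] = {}
        for r in range(1, len(kept) + 1):
            for combo in itertools.combinations(kept, r):
                if check_delta_set(fg.graph, combo, delta):
                    spec = frozenset(fg.family_of[v] for v in combo)
                    table.setdefault(spec, []).append(frozenset(combo))
        by_spectrum.append(table)
    spectra = set(by_spectrum[0])
    for table in by_spectrum[1:]:
        spectra &= set(table)
    candidates: list[tuple[frozenset, ...]] = []
    for spec in spectra:
        for tup in itertools.product(*(table[spec] for table in by_spectrum)):
            candidates.append(tuple(tup))
    maximal = [
        t for t in candidates if not any(_dominated(t, o) for o in candidates)
    ]
    teams = [
        FamilyTeam(
            vertex_sets=t,
            family_spectrum=frozenset(
                family_graphs[0].family_of[v] for v in t[0]
            ),
            delta=float(delta),
        )
        for t in maximal
    ]
    teams.sort(key=lambda tm: [[_vkey(v) for v in s] for s in tm.canonical()])
    return teams


# -- worked toy instances --------------------------------------------------


def toy_shared_instance() -> tuple[WeightedGraph, WeightedGraph]:
    """Two hand-crafted 7-vertex graphs over vertices a..g.

    Constructed so that the teams are: 1-team {d, f}; 2-team {c, d, f};
    3-team {a, c, d, f, g}; and {c, d, f, g} is a non-maximal 3-cluster
    (everything else stays a singleton at delta <= 3).
    """
    g = WeightedGraph.from_edges(
        [("d", "f", 1), ("c", "d", 2), ("f", "g", 3), ("a", "c", 3),
         ("a", "b", 10), ("e", "g", 10)],
        name="G",
    )
    h = WeightedGraph.from_edges(
        [("d", "f", 1), ("c", "f", 2), ("d", "g", 3), ("a", "g", 3),
         ("a", "b", 10), ("e", "g", 10)],
        name="H",
    )
    return g, h


def toy_family_instance() -> tuple[FamilyGraph, FamilyGraph]:
    """Two hand-crafted 7-vertex family-labeled graphs.

    The first graph has one vertex per family a..g; the second carries two
    copies of family c (and no family b).  Teams by family set: 1-team
    {d, f}; 2-teams {c, d, f} and {c, e}; 3-team {a, c, d, f, g}; the family
    set {c, d, f, g} is a non-maximal 3-cluster.
    """
    g = WeightedGraph.from_edges(
        [("c", "d", 2), ("d", "f", 1), ("f", "g", 3), ("a", "c", 3),
         ("c", "e", 2), ("a", "b", 10)],
        name="Gfam",
    )
    fg = FamilyGraph(
        graph=g, family_of={v: v for v in "abcdefg"}
    )
    h = WeightedGraph.from_edges(
        [("d", "f", 1), ("c1", "f", 2), ("d", "g", 3), ("a", "g", 3),
         ("c2", "e", 2)],
        name="Hfam",
    )
    fh = FamilyGraph(
        graph=h,
        family_of={"a": "a", "c1": "c", "c2": "c", "d": "d", "e": "e",
                   "f": "f", "g": "g"},
    )
    return fg, fh


def max_matrix_counterexample() -> tuple[WeightedGraph, WeightedGraph]:
    """G a path a-b-c (weights 1, 1); H a path a-c-b (weights 1, 1).

    At delta = 1, {a, b, c} is a team (different chains per graph), yet the
    pointwise-max distance matrix thresholded at 1 is edgeless — the reason
    the oracle refines per graph instead of single-linkage on that matrix.
    """
    g = WeightedGraph.from_edges([("a", "b", 1), ("b", "c", 1)], name="Gpath")
    h = WeightedGraph.from_edges([("a", "c", 1), ("c", "b", 1)], name="Hpath")
    return g, h


# -- random team instances -------------------------------------------------


def gen_team_instance(
    seed: int,
    n_shared: int = 10,
    n_graphs: int = 2,
    n_extra: int = 2,
    density: float = 0.3,
    weight_range: tuple[int, int] = (1, 5),
) -> list[WeightedGraph]:
    """Random graphs over a shared vertex set plus per-graph extra vertices."""
    rng = np.random.default_rng(seed)
    shared = [f"s{i:02d}" for i in range(n_shared)]
    graphs = []
    lo, hi = weight_range
    for gi in range(n_graphs):
        verts = shared + [f"g{gi}x{j}" for j in range(n_extra)]
        g = WeightedGraph(name=f"G{gi}")
        for v in verts:
            g.add_vertex(v)
        for a in range(len(verts)):
            for b in range(a + 1, len(verts)):
                if rng.random() < density:
                    g.add_edge(verts[a], verts[b], int(rng.integers(lo, hi + 1)))
        graphs.append(g)
    return graphs


def gen_family_instance(
    seed: int,
    n_families: int = 4,
    n_graphs: int = 2,
    duplication_rate: float = 0.3,
    max_vertices: int = 6,
    density: float = 0.4,
    weight_range: tuple[int, int] = (1, 5),
) -> list[FamilyGraph]:
    """Random family-labeled graphs; every common family has >= 1 member per
    graph, duplicates added at the given rate up to ``max_vertices``."""
    rng = np.random.default_rng(seed)
    fams = [f"f{i}" for i in range(n_families)]
    lo, hi = weight_range
    out = []
    for gi in range(n_graphs):
        family_of = {}
        verts = []
        for fi, fam in enumerate(fams):
            v = f"g{gi}v{fi}a"
            verts.append(v)
            family_of[v] = fam
        for fi, fam in enumerate(fams):
            if len(verts) >= max_vertices:
                break
            if rng.random() < duplication_rate:
                v = f"g{gi}v{fi}b"
                verts.append(v)
                family_of[v] = fam
        g = WeightedGraph(name=f"G{gi}")
        for v in verts:
            g.add_vertex(v)
        for a in range(len(verts)):
            for b in range(a + 1, len(verts)):
                if rng.random() < density:
                    g.add_edge(verts[a], verts[b], int(rng.integers(lo, hi + 1)))
        out.append(FamilyGraph(graph=g, family_of=family_of))
    return out


# -- synthetic Hi-C --------------------------------------------------------


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic Hi-C corpus; identical spec + seed give
    byte-identical outputs."""

    seed: int = 0
    n_genomes: int = 2
    n_chromosomes: int = 2
    bins_per_chromosome: int = 15
    resolution_bp: int = 40_000
    decay_amplitude: float = 30.0
    decay_alpha: float = 1.5
    zero_rate: float = 0.1
    planted_size: int = 3
    planted_count: float = 100.0
    interchromosomal: bool = False
    n_background_genes: int = 20


@dataclass(frozen=True)
class SyntheticGenome:
    name: str
    maps: tuple[HiCMap, ...]
    annotation: GenomeAnnotation


@dataclass(frozen=True)
class SyntheticHiC:
    genomes: tuple[SyntheticGenome, ...]
    planted_families: frozenset
    suggested_delta: float


def _decay_counts(rng, n: int, spec: SyntheticSpec) -> np.ndarray:
    counts = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            base = spec.decay_amplitude * (j - i) ** (-spec.decay_alpha)
            c = float(np.round(base)) + float(rng.poisson(1.0))
            if rng.random() < spec.zero_rate:
                c = 0.0
            counts[i, j] = counts[j, i] = c
    return counts


def gen_synthetic_hic(spec: SyntheticSpec) -> SyntheticHiC:
    """Distance-decaying background counts with empty cells and one planted
    cluster whose gene families receive near-maximum mutual counts in every
    genome (across two chromosomes when ``interchromosomal`` is set)."""
    rng = np.random.default_rng(spec.seed)
    n_fams = spec.n_background_genes
    planted_fams = [f"pf{i}" for i in range(spec.planted_size)]
    background_fams = [f"bf{i}" for i in range(n_fams)]
    r = spec.resolution_bp
    nb = spec.bins_per_chromosome
    genomes = []
    for gi in range(spec.n_genomes):
        chroms = [f"chr{ci+1}" for ci in range(spec.n_chromosomes)]
        counts = {ch: _decay_counts(rng, nb, spec) for ch in chroms}
        inter = None
        # scatter background genes over chromosomes/segments
        genes: list[Gene] = []
        free = [(ch, b) for ch in chroms for b in range(nb)]
        order = rng.permutation(len(free))
        slots = [free[i] for i in order]
        for k, fam in enumerate(background_fams):
            ch, b = slots[k % len(slots)]
            start = b * r + 2_000 + 40 * k
            genes.append(Gene(f"{gi}bg{k}", ch, start, start + 1_000, fam))
        # plant the cluster on dedicated segments
        if spec.interchromosomal and gi == 0:
            # first genome: planted genes split across the first two chromosomes
            placements = [
                (chroms[ci % 2], nb - 1 - 3 * (ci // 2)) for ci in range(spec.planted_size)
            ]
        else:
            # separated segments: joined only through boosted long-range cells,
            # invisible to the sequential (adjacent-cells-only) graph
            placements = [(chroms[0], nb - 1 - 3 * ci) for ci in range(spec.planted_size)]
        for k, (fam, (ch, b)) in enumerate(zip(planted_fams, placements)):
            start = b * r + 10_000
            genes.append(Gene(f"{gi}pl{k}", ch, start, start + 1_000, fam))
        # boost counts between planted segments
        if spec.interchromosomal and gi == 0:
            inter = np.zeros((nb, nb))
            for a in range(spec.planted_size):
                for b in range(a + 1, spec.planted_size):
                    ch_a, seg_a = placements[a]
                    ch_b, seg_b = placements[b]
                    if ch_a == ch_b:
                        m = counts[ch_a]
                        m[seg_a, seg_b] = m[seg_b, seg_a] = spec.planted_count
                    else:
                        i, j = (seg_a, seg_b) if ch_a == chroms[0] else (seg_b, seg_a)
                        inter[i, j] = spec.planted_count
        else:
            for a in range(spec.planted_size):
                for b in range(a + 1, spec.planted_size):
                    m = counts[placements[a][0]]
                    m[placements[a][1], placements[b][1]] = spec.planted_count
                    m[placements[b][1], placements[a][1]] = spec.planted_count
        # every map carries at least one near-max cell so normalization is mild
        maps = [
            HiCMap(chrom_a=ch, chrom_b=ch, resolution_bp=r, counts=counts[ch])
            for ch in chroms
        ]
        for m in maps:
            if m.max_count < spec.planted_count:
                hot = int(rng.integers(0, nb - 1))
                m.counts[hot, hot + 1] = m.counts[hot + 1, hot] = spec.planted_count
        if inter is not None:
            maps.append(
                HiCMap(chrom_a=chroms[0], chrom_b=chroms[1], resolution_bp=r, counts=inter)
            )
        annotation = GenomeAnnotation(
            name=f"genome{gi}",
            genes=tuple(sorted(genes, key=lambda g: (g.chrom, g.start_bp, g.gene_id))),
        )
        genomes.append(
            SyntheticGenome(name=f"genome{gi}", maps=tuple(maps), annotation=annotation)
        )
    # planted cells sit at the corpus maximum, so their distance is ~1 after
    # normalization; delta = 10 comfortably joins them and excludes the
    # background (adjacent-segment distances are ~ max - amplitude >> 10)
    return SyntheticHiC(
        genomes=tuple(genomes),
        planted_families=frozenset(planted_fams),
        suggested_delta=10.0,
    )


# -- synthetic GO ----------------------------------------------------------


def gen_synthetic_go(
    seed: int,
    n_terms: int = 80,
    n_genes: int = 60,
    module_size: int = 5,
    module_radius: int = 0,
    extra_parent_rate: float = 0.2,
    terms_per_gene: tuple[int, int] = (1, 2),
) -> tuple[GoDag, GoAnnotations, frozenset]:
    """Random rooted DAG with one planted functional module.

    Module genes are annotated to terms within ``module_radius`` hops of a
    randomly chosen deep anchor term (radius 0 = the anchor itself, giving
    within-module dissimilarity 0); background genes are annotated uniformly.
    Returns (dag, annotations, module gene ids).
    """
    rng = np.random.default_rng(seed)
    terms = [f"T{i:03d}" for i in range(n_terms)]
    parents: dict[str, tuple[str, ...]] = {terms[0]: ()}
    for i in range(1, n_terms):
        ps = {terms[int(rng.integers(0, i))]}
        if rng.random() < extra_parent_rate and i > 1:
            ps.add(terms[int(rng.integers(0, i))])
        parents[terms[i]] = tuple(sorted(ps))
    dag = GoDag(parents=parents, namespace="biological_process")
    deep = [t for t in terms if dag.depth[t] >= 2] or terms[1:]
    anchor = deep[int(rng.integers(0, len(deep)))]
    near = sorted(t for t, h in dag.hop_distances(anchor).items() if h <= module_radius)
    lo, hi = terms_per_gene
    table: dict[str, frozenset] = {}
    module_genes = [f"mg{i}" for i in range(module_size)]
    for g in module_genes:
        table[g] = frozenset({near[int(rng.integers(0, len(near)))]})
    for i in range(n_genes - module_size):
        k = int(rng.integers(lo, hi + 1))
        picks = rng.choice(len(terms), size=min(k, n_terms), replace=False)
        table[f"bg{i}"] = frozenset(terms[p] for p in picks)
    return dag, GoAnnotations(terms_of=table), frozenset(module_genes)
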