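"""Rank gene cluster candidates by GO-based functional dissimilarity.

The dissimilarity between two annotated genes is the minimum over their term
pairs of (number of separating nodes on the shortest undirected path)
divided by the sum of the two terms' depths.  A cluster's penalty sums, per
member, the gap between its nearest co-member and its nearest gene
genome-wide; the penalty is compared against pools of equally sized random
gene sets to obtain an empirical p-value.
"""

from __future__ import annotations

import logging
import math
from collections import deque
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

BIOLOGICAL_PROCESS = "biological_process"


class OboFormatError(ValueError):
    """Malformed or inconsistent ontology input."""


class UnscorableClusterError(ValueError):
    """Cluster has fewer than two annotated genes."""


def _normalize_namespace(ns: str) -> str:
    return ns.strip().lower().replace(" ", "_")


@dataclass
class GoDag:
    """Rooted is-a DAG of one GO namespace with per-term depths.

    ``depth_mode`` selects the depth convention: ``shortest`` (default) or
    ``longest`` root-to-term path, counted in edges.
    """

    parents: Mapping[str, tuple[str, ...]]
    namespace: str = BIOLOGICAL_PROCESS
    depth_mode: str = "shortest"
    root: str = field(init=False)
    depth: dict[str, int] = field(init=False)

    def __post_init__(self):
        dg = nx.DiGraph()
        dg.add_nodes_from(self.parents)
        for child, ps in self.parents.items():
            for p in ps:
                if p not in self.parents:
                    raise OboFormatError(f"term {child} has unknown parent {p}")
                dg.add_edge(child, p)
        if not nx.is_directed_acyclic_graph(dg):
            raise OboFormatError("the term hierarchy contains a cycle")
        roots = sorted(t for t, ps in self.parents.items() if not ps)
        if len(roots) == 0:
            raise OboFormatError("no root term in the namespace")
        if len(roots) > 1:
            raise OboFormatError(f"multiple roots in the namespace: {roots}")
        self.root = roots[0]
        children: dict[str, list[str]] = {t: [] for t in self.parents}
        for child, ps in self.parents.items():
            for p in ps:
                children[p].append(child)
        if self.depth_mode == "shortest":
            depth = {self.root: 0}
            queue = deque([self.root])
            while queue:
                t = queue.popleft()
                for ch in children[t]:
                    if ch not in depth:
                        depth[ch] = depth[t] + 1
                        queue.append(ch)
        elif self.depth_mode == "longest":
            depth = {self.root: 0}
            for t in reversed(list(nx.topological_sort(dg))):  # root first
                for ch in children[t]:
                    depth[ch] = max(depth.get(ch, 0), depth[t] + 1)
        else:
            raise ValueError(f"unknown depth mode {self.depth_mode!r}")
        missing = set(self.parents) - set(depth)
        if missing:
            raise OboFormatError(
                f"terms unreachable from the root: {sorted(missing)[:5]}"
            )
        self.depth = depth
        self._undirected = dg.to_undirected(as_view=False)
        self._sep_cache: dict[str, dict[str, int]] = {}

    @property
    def terms(self) -> frozenset:
        return frozenset(self.parents)

    def hop_distances(self, term: str) -> dict[str, int]:
        if term not in self.parents:
            raise OboFormatError(f"unknown term {term!r}")
        cached = self._sep_cache.get(term)
        if cached is None:
            cached = dict(nx.single_source_shortest_path_length(self._undirected, term))
            self._sep_cache[term] = cached
        return cached


@dataclass(frozen=True)
class GoAnnotations:
    """Mapping gene -> non-empty set of GO terms; the annotated universe."""

    terms_of: Mapping[str, frozenset]

    @property
    def genes(self) -> frozenset:
        return frozenset(self.terms_of)

    def __contains__(self, gene: str) -> bool:
        return gene in self.terms_of


def parse_obo(path, namespace: str = BIOLOGICAL_PROCESS, depth_mode: str = "shortest") -> GoDag:
    """Minimal OBO v1.2 reader: [Term] stanzas with id / namespace / is_a /
    is_obsolete.  Terms outside the namespace and obsolete terms are dropped;
    parent links leaving the namespace are cut."""
    namespace = _normalize_namespace(namespace)
    raw: dict[str, dict] = {}
    current: dict | None = None
    with open(path) as fh:
        for line in fh:
            line = line.split("!")[0].strip()
            if line == "[Term]":
                current = {"parents": [], "namespace": None, "obsolete": False, "id": None}
                continue
            if line.startswith("["):
                current = None
                continue
            if current is None or not line:
                continue
            if line.startswith("id:"):
                current["id"] = line[3:].strip()
                raw[current["id"]] = current
            elif line.startswith("namespace:"):
                current["namespace"] = _normalize_namespace(line[10:])
            elif line.startswith("is_a:"):
                current["parents"].append(line[5:].strip().split()[0])
            elif line.startswith("is_obsolete:"):
                current["obsolete"] = line[12:].strip() == "true"
    kept = {
        tid
        for tid, t in raw.items()
        if not t["obsolete"] and (t["namespace"] or namespace) == namespace
    }
    if not kept:
        raise OboFormatError(f"{path}: no terms in namespace {namespace!r}")
    parents = {
        tid: tuple(p for p in raw[tid]["parents"] if p in kept) for tid in sorted(kept)
    }
    return GoDag(parents=parents, namespace=namespace, depth_mode=depth_mode)


def parse_gene_annotations(path, dag: GoDag) -> GoAnnotations:
    """GAF-like TSV ``gene_id<TAB>go_term``; unknown terms dropped with a
    warning, genes left without terms are excluded."""
    table: dict[str, set] = {}
    dropped_terms = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "!")):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise OboFormatError(f"{path}:{lineno}: expected 'gene_id<TAB>go_term'")
            gene, term = parts[0], parts[1]
            if term not in dag.terms:
                dropped_terms += 1
                continue
            table.setdefault(gene, set()).add(term)
    if dropped_terms:
        logger.warning("%s: dropped %d annotations to unknown terms", path, dropped_terms)
    return GoAnnotations(terms_of={g: frozenset(ts) for g, ts in table.items() if ts})


def load_go(obo_path, gaf_path, namespace: str = "Biological Process",
            depth_mode: str = "shortest") -> tuple[GoDag, GoAnnotations]:
    dag = parse_obo(obo_path, namespace=namespace, depth_mode=depth_mode)
    return dag, parse_gene_annotations(gaf_path, dag)


def term_path_separation(dag: GoDag, u: str, v: str) -> float:
    """Number of intermediate vertices on the shortest undirected path
    between two terms; 0 for identical or adjacent terms, inf when
    disconnected (defensive — cannot occur within one rooted namespace)."""
    hops = dag.hop_distances(u).get(v)
    if v not in dag.parents:
        raise OboFormatError(f"unknown term {v!r}")
    if hops is None:
        return math.inf
    return max(hops - 1, 0)


def gene_gfd(dag: GoDag, annotations: GoAnnotations, g1: str, g2: str) -> float:
    """Functional dissimilarity: min over annotated term pairs of
    separation / (depth + depth).  0/0 (both terms the root) is defined as 0,
    the shared-term limit."""
    if g1 not in annotations or g2 not in annotations:
        missing = g1 if g1 not in annotations else g2
        raise ValueError(f"gene {missing!r} has no GO annotation")
    best = math.inf
    for u in annotations.terms_of[g1]:
        hops = dag.hop_distances(u)
        du = dag.depth[u]
        for v in annotations.terms_of[g2]:
            sep = max(hops.get(v, math.inf) - 1, 0)
            if sep == 0:
                return 0.0
            denom = du + dag.depth[v]
            val = sep / denom if denom > 0 else math.inf
            if val < best:
                best = val
    return best


class GfdScorer:
    """Caches pairwise dissimilarities and per-gene genome-wide minima.

    The quadratic gene-pair table is filled lazily; genome-wide nearest
    values are computed once per gene and reused across penalty and pool
    evaluations.
    """

    def __init__(self, dag: GoDag, annotations: GoAnnotations, genome_genes: Iterable[str] | None = None):
        self.dag = dag
        self.annotations = annotations
        universe = set(annotations.genes if genome_genes is None else genome_genes)
        unannotated = universe - annotations.genes
        if unannotated:
            logger.info("excluding %d unannotated genes from scoring", len(unannotated))
        self.genome = tuple(sorted(universe & annotations.genes))
        self._pair: dict[tuple[str, str], float] = {}
        self._nearest: dict[str, float] = {}

    def gfd(self, g1: str, g2: str) -> float:
        key = (g1, g2) if g1 <= g2 else (g2, g1)
        val = self._pair.get(key)
        if val is None:
            val = gene_gfd(self.dag, self.annotations, g1, g2)
            self._pair[key] = val
        return val

    def nearest_genomewide(self, g: str) -> float:
        val = self._nearest.get(g)
        if val is None:
            val = min(
                (self.gfd(g, other) for other in self.genome if other != g),
                default=math.inf,
            )
            self._nearest[g] = val
        return val

    def cluster_penalty(self, cluster_genes: Iterable[str]) -> float:
        cluster = sorted(set(cluster_genes) & set(self.genome))
        if len(cluster) < 2:
            raise UnscorableClusterError(
                f"cluster has {len(cluster)} annotated genes; need >= 2"
            )
        total = 0.0
        for g in cluster:
            in_cluster = min(self.gfd(g, other) for other in cluster if other != g)
            total += in_cluster - self.nearest_genomewide(g)
        return total


def cluster_penalty(
    dag: GoDag,
    annotations: GoAnnotations,
    cluster_genes: Iterable[str],
    genome_genes: Iterable[str],
    scorer: GfdScorer | None = None,
) -> float:
    """Sum over cluster genes of (nearest co-member GFD - nearest genome-wide
    GFD); non-negative because the genome-wide minimum runs over a superset."""
    if scorer is None:
        scorer = GfdScorer(dag, annotations, genome_genes)
    return scorer.cluster_penalty(cluster_genes)


def sample_null(
    dag: GoDag,
    annotations: GoAnnotations,
    genome_genes: Iterable[str],
    size: int,
    pool_size: int,
    seed: int,
    scorer: GfdScorer | None = None,
) -> np.ndarray:
    """Pool of penalties of uniformly drawn size-subsets of the annotated genome."""
    if scorer is None:
        scorer = GfdScorer(dag, annotations, genome_genes)
    if size < 2:
        raise ValueError(f"cluster size must be >= 2, got {size}")
    if size > len(scorer.genome):
        raise ValueError(
            f"cluster size {size} exceeds annotated genome size {len(scorer.genome)}"
        )
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    rng = np.random.default_rng(seed)
    genome = np.array(scorer.genome, dtype=object)
    out = np.empty(pool_size)
    for i in range(pool_size):
        draw = rng.choice(genome, size=size, replace=False)
        out[i] = scorer.cluster_penalty(draw)
    return out


def empirical_pvalue(phi: float, pool: np.ndarray) -> float:
    """(count of pool penalties <= phi, plus one) / (pool size plus one)."""
    pool = np.asarray(pool)
    if pool.size == 0:
        raise ValueError("empty penalty pool")
    return (int(np.count_nonzero(pool <= phi)) + 1) / (pool.size + 1)


@dataclass(frozen=True)
class PenaltyResult:
    cluster_id: str
    size: int
    phi: float
    p_value: float
    pool_size: int

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def rank_clusters(results: Iterable[PenaltyResult]) -> list[PenaltyResult]:
    """Ascending p, then ascending penalty, descending size, cluster id."""
    return sorted(
        results, key=lambda r: (r.p_value, r.phi, -r.size, str(r.cluster_id))
    )


def score_clusters(
    dag: GoDag,
    annotations: GoAnnotations,
    clusters: Mapping[str, Iterable[str]],
    genome_genes: Iterable[str],
    pool_size: int,
    seed: int,
) -> tuple[list[PenaltyResult], list[str]]:
    """Score and rank clusters; returns (ranked results, unscorable ids).

    Null pools are drawn once per distinct cluster size and cached; the pool
    seed is derived from the base seed and the size so pools are reproducible
    independently of cluster order.
    """
    scorer = GfdScorer(dag, annotations, genome_genes)
    pools: dict[int, np.ndarray] = {}
    results, unscorable = [], []
    for cid in sorted(clusters, key=str):
        genes = set(clusters[cid])
        annotated = sorted(genes & set(scorer.genome))
        if len(annotated) < 2:
            unscorable.append(cid)
            continue
        phi = scorer.cluster_penalty(annotated)
        n = len(annotated)
        if n not in pools:
            pools[n] = sample_null(
                dag, annotations, scorer.genome, n, pool_size, seed + n, scorer=scorer
            )
        results.append(
            PenaltyResult(
                cluster_id=str(cid),
                size=n,
                phi=phi,
                p_value=empirical_pvalue(phi, pools[n]),
                pool_size=pool_size,
            )
        )
    return rank_clusters(results), unscorable
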