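"""Build weighted gene graphs from Hi-C contact maps and gene annotations.

Contact counts are closeness scores; they become distances through
``max + 1 - count`` after all maps have been rescaled to a common maximum
(the average of the per-map maxima across every map of every genome).  Empty
cells receive no correction — their distance is ``max + 1``, the largest
finite value — except adjacent-diagonal cells, which are filled with the
same base-pair estimator used for genes sharing a segment.

Two graph flavors are produced per genome: the *spatial* graph uses every
map cell, the *sequential* graph only same-segment and adjacent-segment
relations, i.e. identical one-dimensional distances without any
three-dimensional shortcuts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .family_teams import FamilyGraph, FamilyTeam
from .graph_core import WeightedGraph

logger = logging.getLogger(__name__)

ESTIMATOR_MODELS = ("interpolate_distance", "count_per_bp")


class HiCFormatError(ValueError):
    """Malformed Hi-C matrix or annotation file."""


class EmptyMapError(ValueError):
    """A map without any positive count cannot be normalized."""


@dataclass
class HiCMap:
    """Contact-count matrix for one chromosome (pair) at a fixed resolution."""

    chrom_a: str
    chrom_b: str
    resolution_bp: int
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise HiCFormatError("counts must be a 2-D matrix")
        if (self.counts < 0).any():
            raise HiCFormatError("negative contact counts")
        if self.resolution_bp <= 0:
            raise HiCFormatError(f"invalid resolution {self.resolution_bp}")
        if self.is_intra:
            n, m = self.counts.shape
            if n != m:
                raise HiCFormatError(
                    f"intrachromosomal map must be square, got {n}x{m}"
                )
            asym = np.sum(~np.isclose(self.counts, self.counts.T))
            if asym:
                logger.warning(
                    "map %s: symmetrized %d asymmetric cell pairs (taking the max)",
                    self.chrom_a,
                    asym // 2,
                )
            self.counts = np.maximum(self.counts, self.counts.T)

    @property
    def is_intra(self) -> bool:
        return self.chrom_a == self.chrom_b

    @property
    def max_count(self) -> float:
        return float(self.counts.max()) if self.counts.size else 0.0


def read_hic_map(
    path,
    format: str,
    resolution_bp: int,
    chrom_a: str,
    chrom_b: str | None = None,
    n_bins: tuple[int, int] | None = None,
) -> HiCMap:
    """Read a dense whitespace matrix or sparse ``bin_i bin_j count`` triples."""
    chrom_b = chrom_b if chrom_b is not None else chrom_a
    if format == "dense":
        rows = []
        width = None
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                try:
                    row = [float(x) for x in line.split()]
                except ValueError as e:
                    raise HiCFormatError(f"{path}:{lineno}: {e}") from None
                if width is None:
                    width = len(row)
                elif len(row) != width:
                    raise HiCFormatError(
                        f"{path}:{lineno}: ragged row ({len(row)} != {width} columns)"
                    )
                if any(x < 0 for x in row):
                    raise HiCFormatError(f"{path}:{lineno}: negative count")
                rows.append(row)
        if not rows:
            raise HiCFormatError(f"{path}: empty matrix")
        counts = np.array(rows)
    elif format == "sparse":
        triples = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) != 3:
                    raise HiCFormatError(
                        f"{path}:{lineno}: expected 'bin_i bin_j count'"
                    )
                try:
                    i, j, c = int(parts[0]), int(parts[1]), float(parts[2])
                except ValueError as e:
                    raise HiCFormatError(f"{path}:{lineno}: {e}") from None
                if i < 0 or j < 0:
                    raise HiCFormatError(f"{path}:{lineno}: negative bin index")
                if c < 0:
                    raise HiCFormatError(f"{path}:{lineno}: negative count")
                triples.append((i, j, c))
        if n_bins is not None:
            nr, nc = n_bins
        else:
            nr = max((t[0] for t in triples), default=-1) + 1
            nc = max((t[1] for t in triples), default=-1) + 1
            if chrom_a == chrom_b:
                nr = nc = max(nr, nc)
        counts = np.zeros((nr, nc))
        for i, j, c in triples:
            if i >= nr or j >= nc:
                raise HiCFormatError(
                    f"{path}: bin ({i},{j}) outside declared shape {nr}x{nc}"
                )
            counts[i, j] = max(counts[i, j], c)
            if chrom_a == chrom_b:
                counts[j, i] = max(counts[j, i], c)
    else:
        raise HiCFormatError(f"unknown Hi-C format {format!r}")
    return HiCMap(chrom_a=chrom_a, chrom_b=chrom_b, resolution_bp=resolution_bp, counts=counts)


def compute_scale(maps: Sequence[HiCMap]) -> float:
    """Average of the per-map maximum contact counts, across all maps."""
    if not maps:
        raise EmptyMapError("no maps supplied")
    maxima = [m.max_count for m in maps]
    if all(x == 0 for x in maxima):
        raise EmptyMapError("all maps are empty; nothing to normalize")
    return float(np.mean(maxima))


def normalize_map(hic: HiCMap, c: float) -> HiCMap:
    """Rescale so the map maximum equals the shared constant ``c``."""
    mx = hic.max_count
    if mx <= 0:
        raise EmptyMapError(f"map {hic.chrom_a}/{hic.chrom_b} has no positive count")
    return HiCMap(
        chrom_a=hic.chrom_a,
        chrom_b=hic.chrom_b,
        resolution_bp=hic.resolution_bp,
        counts=hic.counts * (c / mx),
    )


def adjacency_mean(hic: HiCMap) -> float:
    """Mean of the non-empty adjacent-diagonal cells M[i, i+1] (intra only)."""
    if not hic.is_intra:
        raise ValueError("adjacency mean is defined for intrachromosomal maps")
    diag = np.diagonal(hic.counts, offset=1)
    nonempty = diag[diag > 0]
    if nonempty.size == 0:
        logger.warning(
            "map %s: all adjacent-diagonal cells empty; adjacency mean set to 0",
            hic.chrom_a,
        )
        return 0.0
    return float(nonempty.mean())


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    start_bp: int
    end_bp: int
    family_id: str

    def __post_init__(self):
        if not self.start_bp < self.end_bp:
            raise HiCFormatError(
                f"gene {self.gene_id}: start {self.start_bp} not < end {self.end_bp}"
            )

    @property
    def midpoint(self) -> int:
        return (self.start_bp + self.end_bp) // 2


@dataclass(frozen=True)
class GenomeAnnotation:
    """Gene records of one genome; 0-based half-open coordinates."""

    name: str
    genes: tuple[Gene, ...]

    def __post_init__(self):
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            dup = sorted({x for x in ids if ids.count(x) > 1})
            raise HiCFormatError(f"duplicate gene ids: {dup[:5]}")

    def by_chrom(self) -> dict[str, list[Gene]]:
        out: dict[str, list[Gene]] = {}
        for g in self.genes:
            out.setdefault(g.chrom, []).append(g)
        for genes in out.values():
            genes.sort(key=lambda g: (g.midpoint, g.gene_id))
        return out


def read_annotation(path, name: str) -> GenomeAnnotation:
    """BED-like TSV: chrom, start, end, gene_id, family_id."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise HiCFormatError(f"{path}:{lineno}: expected 5 tab-separated columns")
            chrom, start, end, gid, fam = parts[:5]
            try:
                genes.append(Gene(gid, chrom, int(start), int(end), fam))
            except ValueError as e:
                raise HiCFormatError(f"{path}:{lineno}: {e}") from None
    return GenomeAnnotation(name=name, genes=tuple(genes))


def assign_genes(annotation: GenomeAnnotation, resolution_bp: int) -> dict[str, int]:
    """Segment index per gene: floor(midpoint / resolution)."""
    return {g.gene_id: g.midpoint // resolution_bp for g in annotation.genes}


def contact_to_distance(hic: HiCMap, i: int, j: int) -> float:
    """Distance of a (normalized) map cell: max + 1 - count; empty -> max + 1."""
    return hic.max_count + 1.0 - float(hic.counts[i, j])


def intra_segment_distance(
    bp_between_midpoints: float,
    adjacency_mean: float,
    resolution_bp: int,
    map_max: float,
    model: str = "interpolate_distance",
) -> float:
    """Distance estimate for genes closer than one segment on the sequence.

    The default model scales the mean adjacent-segment distance by the
    base-pair fraction, so ``b = r`` reproduces that distance and the
    estimate vanishes as ``b -> 0``.  The ``count_per_bp`` model reads the
    per-base-pair contact score ``C / r`` literally as a distance rate.
    """
    b = float(bp_between_midpoints)
    if b < 0:
        raise ValueError(f"negative base-pair gap {b}")
    if model == "interpolate_distance":
        return (b / resolution_bp) * (map_max + 1.0 - adjacency_mean)
    if model == "count_per_bp":
        return b * adjacency_mean / resolution_bp
    raise ValueError(f"unknown estimator model {model!r}")


def _segment_genes(
    annotation: GenomeAnnotation, resolution_bp: int, n_bins: int, chrom: str
) -> dict[int, list[Gene]]:
    """Genes of one chromosome grouped by segment, midpoint-ordered; genes
    beyond the map extent are excluded (flagged in the log)."""
    out: dict[int, list[Gene]] = {}
    beyond = 0
    for g in annotation.by_chrom().get(chrom, []):
        seg = g.midpoint // resolution_bp
        if seg >= n_bins:
            beyond += 1
            continue
        out.setdefault(seg, []).append(g)
    if beyond:
        logger.warning(
            "%s/%s: %d genes beyond the map extent, excluded from map edges",
            annotation.name,
            chrom,
            beyond,
        )
    return out


def _add_chain_edges(
    graph: WeightedGraph,
    genes: list[Gene],
    cmean: float,
    resolution_bp: int,
    map_max: float,
    model: str,
    delta_prune: float | None,
) -> None:
    """Chain same-segment genes in midpoint order with estimator edges."""
    for a, b in zip(genes, genes[1:]):
        w = intra_segment_distance(
            b.midpoint - a.midpoint, cmean, resolution_bp, map_max, model
        )
        if delta_prune is None or w <= delta_prune:
            graph.add_edge(a.gene_id, b.gene_id, w)


def _add_cell_edges(
    graph: WeightedGraph,
    hic: HiCMap,
    genes_i: list[Gene],
    genes_j: list[Gene],
    i: int,
    j: int,
    cmean: float,
    model: str,
    delta_prune: float | None,
) -> None:
    """Edges between all gene pairs of segments i and j of one map."""
    empty_adjacent = (
        hic.is_intra and abs(i - j) == 1 and hic.counts[i, j] == 0
    )
    w_cell = contact_to_distance(hic, i, j)
    for ga in genes_i:
        for gb in genes_j:
            if ga.gene_id == gb.gene_id:
                continue
            if empty_adjacent:
                w = intra_segment_distance(
                    abs(gb.midpoint - ga.midpoint),
                    cmean,
                    hic.resolution_bp,
                    hic.max_count,
                    model,
                )
            else:
                w = w_cell
            if delta_prune is None or w <= delta_prune:
                graph.add_edge(ga.gene_id, gb.gene_id, w)


def _base_graph(annotation: GenomeAnnotation) -> tuple[WeightedGraph, dict[str, str]]:
    graph = WeightedGraph(name=annotation.name)
    family_of = {}
    for g in annotation.genes:
        graph.add_vertex(g.gene_id)
        family_of[g.gene_id] = g.family_id
    return graph, family_of


def build_spatial_graph(
    annotation: GenomeAnnotation,
    maps: Sequence[HiCMap],
    model: str = "interpolate_distance",
    delta_prune: float | None = None,
) -> FamilyGraph:
    """Gene graph using every cell of every (normalized) map of the genome.

    For each map cell (i, j), i != j, with at least one gene in each segment,
    all cross gene pairs receive the cell's contact distance (including
    interchromosomal maps).  Genes sharing a segment are chained in midpoint
    order with estimator edges; empty adjacent-diagonal cells are filled with
    the same estimator using the actual gene-pair midpoint gap.
    """
    graph, family_of = _base_graph(annotation)
    cmeans = {m.chrom_a: adjacency_mean(m) for m in maps if m.is_intra}
    covered = {m.chrom_a for m in maps} | {m.chrom_b for m in maps}
    for chrom in annotation.by_chrom():
        if chrom not in covered:
            logger.warning(
                "%s/%s: no Hi-C map; genes stay isolated", annotation.name, chrom
            )
    for hic in maps:
        if hic.is_intra:
            segs = _segment_genes(annotation, hic.resolution_bp, hic.counts.shape[0], hic.chrom_a)
            cmean = cmeans[hic.chrom_a]
            occupied = sorted(segs)
            for i in occupied:
                _add_chain_edges(
                    graph, segs[i], cmean, hic.resolution_bp, hic.max_count, model, delta_prune
                )
            for a, i in enumerate(occupied):
                for j in occupied[a + 1 :]:
                    _add_cell_edges(
                        graph, hic, segs[i], segs[j], i, j, cmean, model, delta_prune
                    )
        else:
            segs_a = _segment_genes(annotation, hic.resolution_bp, hic.counts.shape[0], hic.chrom_a)
            segs_b = _segment_genes(annotation, hic.resolution_bp, hic.counts.shape[1], hic.chrom_b)
            for i, genes_i in segs_a.items():
                for j, genes_j in segs_b.items():
                    _add_cell_edges(
                        graph, hic, genes_i, genes_j, i, j, 0.0, model, delta_prune
                    )
    return FamilyGraph(graph=graph, family_of=family_of)


def build_sequential_graph(
    annotation: GenomeAnnotation,
    maps: Sequence[HiCMap],
    model: str = "interpolate_distance",
    delta_prune: float | None = None,
) -> FamilyGraph:
    """Gene graph restricted to same-segment and adjacent-segment relations.

    Identical one-dimensional distances as the spatial graph, without
    three-dimensional shortcuts.  Only intrachromosomal maps are used.
    """
    graph, family_of = _base_graph(annotation)
    for hic in maps:
        if not hic.is_intra:
            continue
        segs = _segment_genes(annotation, hic.resolution_bp, hic.counts.shape[0], hic.chrom_a)
        cmean = adjacency_mean(hic)
        for i in sorted(segs):
            _add_chain_edges(
                graph, segs[i], cmean, hic.resolution_bp, hic.max_count, model, delta_prune
            )
            if i + 1 in segs:
                _add_cell_edges(
                    graph, hic, segs[i], segs[i + 1], i, i + 1, cmean, model, delta_prune
                )
    return FamilyGraph(graph=graph, family_of=family_of)


def spatial_gain(
    teams_3d: Sequence[FamilyTeam],
    teams_1d: Sequence[FamilyTeam],
    reference_genome: int = 0,
) -> float:
    """Average number of genes per 3D team found in no 1D team of size >= 2.

    Singleton teams are not clusters: only 3D teams of size >= 2 enter the
    average (identical 3D and 1D reports therefore give 0).
    """
    clusters_3d = [t for t in teams_3d if t.size >= 2]
    if not clusters_3d:
        return 0.0
    covered: set = set()
    for t in teams_1d:
        if t.size >= 2:
            covered |= t.vertex_sets[reference_genome]
    gains = [
        len(t.vertex_sets[reference_genome] - covered) for t in clusters_3d
    ]
    return float(np.mean(gains))
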