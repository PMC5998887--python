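"""Plain-text readers/writers: edge lists, family tables, team reports.

All outputs are tab-separated with ``#``-prefixed comment headers so runs
are diff-able and byte-stable.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

from .family_teams import FamilyGraph, FamilyTeam
from .graph_core import TeamPartition, WeightedGraph, _vkey

logger = logging.getLogger(__name__)


class EdgeListFormatError(ValueError):
    pass


def write_edge_list(graph: WeightedGraph, path, header: Mapping[str, object] | None = None) -> None:
    """Tab-separated ``u v weight``; a comment header names the graph and
    carries optional provenance key/value pairs."""
    with open(path, "w") as fh:
        fh.write(f"# graph\t{graph.name or ''}\n")
        for key, val in (header or {}).items():
            fh.write(f"# {key}\t{val}\n")
        for v in sorted(graph.vertices, key=_vkey):
            fh.write(f"# vertex\t{v}\n")
        for u, v, w in sorted(graph.edges(), key=lambda e: (_vkey(e[0]), _vkey(e[1]))):
            fh.write(f"{u}\t{v}\t{w:.10g}\n")


def read_edge_list(path) -> WeightedGraph:
    graph = WeightedGraph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].strip().split("\t")
                if parts[0] == "graph" and len(parts) > 1 and parts[1]:
                    graph.name = parts[1]
                elif parts[0] == "vertex" and len(parts) > 1:
                    graph.add_vertex(parts[1])
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise EdgeListFormatError(
                    f"{path}:{lineno}: expected 'u<TAB>v<TAB>weight'"
                )
            try:
                graph.add_edge(parts[0], parts[1], float(parts[2]))
            except ValueError as e:
                raise EdgeListFormatError(f"{path}:{lineno}: {e}") from None
    return graph


def write_family_table(family_of: Mapping, path) -> None:
    """TSV ``vertex_id<TAB>family_id``."""
    with open(path, "w") as fh:
        fh.write("# vertex_id\tfamily_id\n")
        for v in sorted(family_of, key=_vkey):
            fh.write(f"{v}\t{family_of[v]}\n")


def read_family_table(path) -> dict:
    out = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise EdgeListFormatError(
                    f"{path}:{lineno}: expected 'vertex_id<TAB>family_id'"
                )
            out[parts[0]] = parts[1]
    return out


def write_team_partition(partition: TeamPartition, path) -> None:
    """TSV ``team_id delta size members`` (members comma-joined, sorted)."""
    with open(path, "w") as fh:
        fh.write("# team_id\tdelta\tsize\tmembers\n")
        for i, team in enumerate(partition.teams):
            members = ",".join(str(v) for v in team)
            fh.write(f"t{i}\t{partition.delta:.10g}\t{len(team)}\t{members}\n")


def write_family_teams(
    teams: Sequence[FamilyTeam], genome_names: Sequence[str], path
) -> None:
    """TSV ``team_id delta family_spectrum`` then one member column per graph."""
    with open(path, "w") as fh:
        cols = "\t".join(f"members_{n}" for n in genome_names)
        fh.write(f"# team_id\tdelta\tfamily_spectrum\t{cols}\n")
        for i, team in enumerate(teams):
            spectrum = ",".join(sorted(str(f) for f in team.family_spectrum))
            cols = "\t".join(
                ",".join(str(v) for v in members) for members in team.canonical()
            )
            fh.write(f"t{i}\t{team.delta:.10g}\t{spectrum}\t{cols}\n")


def write_annotation(annotation, path) -> None:
    """BED-like TSV ``chrom start end gene_id family_id`` (0-based half-open)."""
    with open(path, "w") as fh:
        fh.write("# chrom\tstart\tend\tgene_id\tfamily_id\n")
        for g in annotation.genes:
            fh.write(f"{g.chrom}\t{g.start_bp}\t{g.end_bp}\t{g.gene_id}\t{g.family_id}\n")


def write_dense_map(hic, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# hic\t{hic.chrom_a}\t{hic.chrom_b}\t{hic.resolution_bp}\n")
        for row in hic.counts:
            fh.write(" ".join(f"{x:.10g}" for x in row) + "\n")


def write_obo(dag, path) -> None:
    """OBO v1.2 subset writer (id, namespace, is_a) for one namespace."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        for term in sorted(dag.parents):
            fh.write(f"\n[Term]\nid: {term}\nname: {term}\nnamespace: {dag.namespace}\n")
            for p in dag.parents[term]:
                fh.write(f"is_a: {p}\n")


def write_gaf(annotations, path) -> None:
    """GAF-like TSV ``gene_id<TAB>go_term``."""
    with open(path, "w") as fh:
        fh.write("# gene_id\tgo_term\n")
        for gene in sorted(annotations.terms_of):
            for term in sorted(annotations.terms_of[gene]):
                fh.write(f"{gene}\t{term}\n")


def read_family_teams(path) -> tuple[list[FamilyTeam], list[str]]:
    """Inverse of :func:`write_family_teams`; returns (teams, genome names)."""
    teams: list[FamilyTeam] = []
    genome_names: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].strip().split("\t")
                genome_names = [
                    c[len("members_"):] for c in parts if c.startswith("members_")
                ]
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise EdgeListFormatError(f"{path}:{lineno}: too few columns")
            delta = float(parts[1])
            spectrum = frozenset(parts[2].split(",")) if parts[2] else frozenset()
            vertex_sets = tuple(
                frozenset(col.split(",")) if col else frozenset() for col in parts[3:]
            )
            teams.append(
                FamilyTeam(vertex_sets=vertex_sets, family_spectrum=spectrum, delta=delta)
            )
    return teams, genome_names
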