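# deltateams

Discovery of **delta-teams** — maximal common single-linkage clusters under a
per-graph shortest-path distance bound δ — in two or more weighted undirected
graphs, with or without gene-family labels, plus the full pipeline that turns
Hi-C contact maps and gene annotations into such graphs and ranks the
resulting spatial gene cluster candidates by a GO-based functional-coherence
penalty with empirical p-values.

## Concepts

* A **δ-set** of a graph is a vertex set in which every pair of members is
  linked by a chain of members whose consecutive shortest-path distances are
  ≤ δ (paths may route through non-members).
* A **δ-team** is a maximal set that is a δ-set in every input graph over the
  shared vertex set; teams partition that set. With **families**, teams are
  tuples of per-graph vertex sets with identical family spectra; they may
  overlap and form no partition.
* Hi-C contact counts become distances via `max + 1 − count` after all maps
  are rescaled to a shared maximum (the average per-map maximum). Genes
  sharing or adjacent to a segment are connected through a base-pair
  interpolation estimator.
* Clusters are ranked by the **gene cluster penalty**: per member, the gap
  between its nearest functional neighbour (GO-based dissimilarity) inside
  the cluster and genome-wide, compared against per-size pools of random
  gene sets.

## Layout

| module | contents |
| --- | --- |
| `deltateams.graph_core` | `WeightedGraph`, bounded simultaneous traversal (`smallmax`), divide-and-conquer `decompose`, `find_delta_teams`, threshold-graph mode |
| `deltateams.family_teams` | family-labeled variant: `FamilyGraph`, `decompose_families`, `find_delta_teams_families` |
| `deltateams.hic_graphs` | Hi-C map reading/normalization, contact→distance transform, spatial & sequential gene graphs, spatial gain |
| `deltateams.go_scoring` | OBO/GAF reading, GO dissimilarity, cluster penalty, null pools, empirical p-values, ranking |
| `deltateams.synth_oracle` | brute-force reference implementations and seeded synthetic generators (graphs, Hi-C corpora, ontologies) |
| `deltateams.io` | tab-separated edge lists, family tables, team reports |
| `deltateams.cli` | `deltateams` command-line pipeline |

## Command line

```sh
deltateams simulate     --outdir run --seed 4          # synthetic corpus + config
deltateams build-graphs --config run/config.yaml       # normalize maps, build graphs
deltateams find-teams   --config run/config.yaml --min-size 2
deltateams score-go     --config run/config.yaml --teams run/teams_d10.spatial.tsv
deltateams spatial-gain --config run/config.yaml \
    --teams-3d run/teams_d10.spatial.tsv --teams-1d run/teams_d10.sequential.tsv
```

The config is YAML: genome entries (annotation path + map manifest with
format/chromosomes/resolution), a δ value or grid, `mode`
(`direct`/`threshold`), graph `flavor` (`spatial`/`sequential`/`both`), the
intra-segment `estimator` model (`interpolate_distance` or `count_per_bp`),
optional `delta_prune`, GO file paths and pool size, seed and output
directory. Every run writes its resolved config and tool version next to its
outputs. Exit codes: 0 success, 1 usage/config error, 2 data-format error.

Input formats are plain text: dense whitespace matrices or sparse
`bin_i bin_j count` triples per chromosome (pair); BED-like gene annotations
`chrom start end gene_id family_id` (0-based half-open); OBO v1.2 term
stanzas; `gene_id<TAB>go_term` annotations.

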