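import numpy as np
import pytest

from deltateams.family_teams import FamilyTeam, find_delta_teams_families
from deltateams.hic_graphs import (
    EmptyMapError,
    Gene,
    GenomeAnnotation,
    HiCFormatError,
    HiCMap,
    adjacency_mean,
    assign_genes,
    build_sequential_graph,
    build_spatial_graph,
    compute_scale,
    contact_to_distance,
    intra_segment_distance,
    normalize_map,
    read_hic_map,
    spatial_gain,
)


def make_map(counts, chrom="chr1", chrom_b=None, r=40_000):
    return HiCMap(
        chrom_a=chrom, chrom_b=chrom_b or chrom, resolution_bp=r, counts=np.array(counts, float)
    )


class TestReadHiCMap:
    def test_dense_symmetric(self, tmp_path):
        p = tmp_path / "m.txt"
        p.write_text("0 5\n5 0\n")
        m = read_hic_map(p, "dense", 40_000, "chr1")
        assert m.counts.shape == (2, 2)
        assert m.max_count == 5

    def test_sparse_intra_mirrors_triples(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("0\t1\t7\n")
        m = read_hic_map(p, "sparse", 40_000, "chr1", n_bins=(3, 3))
        assert m.counts[0, 1] == 7 and m.counts[1, 0] == 7
        assert m.counts.sum() == 14

    def test_dense_asymmetry_symmetrized_with_warning(self, tmp_path, caplog):
        p = tmp_path / "m.txt"
        p.write_text("0 4\n6 0\n")
        with caplog.at_level("WARNING"):
            m = read_hic_map(p, "dense", 40_000, "chr1")
        assert m.counts[0, 1] == 6 and m.counts[1, 0] == 6
        assert "symmetrized" in caplog.text

    def test_ragged_rows_named_line(self, tmp_path):
        p = tmp_path / "m.txt"
        p.write_text("0 1\n2\n")
        with pytest.raises(HiCFormatError, match=":2"):
            read_hic_map(p, "dense", 40_000, "chr1")

    def test_negative_count_rejected(self, tmp_path):
        p = tmp_path / "m.txt"
        p.write_text("0 -1\n1 0\n")
        with pytest.raises(HiCFormatError):
            read_hic_map(p, "dense", 40_000, "chr1")


class TestNormalization:
    def test_single_map_scale(self):
        assert compute_scale([make_map([[0, 10], [10, 0]])]) == 10

    def test_mean_of_maxima(self):
        maps = [make_map([[0, 10], [10, 0]]), make_map([[0, 30], [30, 0]], chrom="chr2")]
        assert compute_scale(maps) == 20

    def test_equal_maxima(self):
        maps = [make_map([[0, 5], [5, 0]], chrom=f"c{i}") for i in range(3)]
        assert compute_scale(maps) == 5

    def test_all_zero_corpus_rejected(self):
        with pytest.raises(EmptyMapError):
            compute_scale([make_map([[0, 0], [0, 0]])])

    def test_normalize_doubles(self):
        m = normalize_map(make_map([[0, 50], [50, 0]]), 100)
        assert m.counts[0, 1] == 100

    def test_normalize_identity_and_zero_preserved(self):
        m0 = make_map([[0, 7, 0], [7, 0, 3], [0, 3, 0]])
        m = normalize_map(m0, 7)
        assert np.allclose(m.counts, m0.counts)
        assert m.counts[0, 2] == 0

    def test_normalized_maximum_equals_c_exactly(self):
        m = normalize_map(make_map([[0, 3], [3, 0]]), 17.5)
        assert abs(m.max_count - 17.5) <= 1e-9 * 17.5

    def test_zero_max_map_rejected(self):
        with pytest.raises(EmptyMapError):
            normalize_map(make_map([[0, 0], [0, 0]]), 10)


class TestAssignGenes:
    def ann(self, *genes):
        return GenomeAnnotation(name="g", genes=tuple(genes))

    def test_first_segment(self):
        a = self.ann(Gene("g1", "chr1", 0, 100, "f"))
        assert assign_genes(a, 40_000)["g1"] == 0

    def test_midpoint_on_boundary_goes_right(self):
        # midpoint exactly r -> segment 1 (half-open segments)
        a = self.ann(Gene("g1", "chr1", 39_000, 41_000, "f"))
        assert assign_genes(a, 40_000)["g1"] == 1

    def test_spanning_gene_uses_midpoint(self):
        a = self.ann(Gene("g1", "chr1", 30_000, 42_000, "f"))
        assert assign_genes(a, 40_000)["g1"] == 0


class TestContactToDistance:
    def test_direct_substitution(self):
        m = make_map([[0, 4, 10], [4, 0, 1], [10, 1, 0]])
        assert contact_to_distance(m, 0, 1) == 7  # 10 + 1 - 4

    def test_max_count_gives_minimum_distance(self):
        m = make_map([[0, 10], [10, 0]])
        assert contact_to_distance(m, 0, 1) == 1

    def test_empty_cell_gives_max_plus_one(self):
        m = make_map([[0, 0, 10], [0, 0, 10], [10, 10, 0]])
        assert contact_to_distance(m, 0, 1) == 11

    def test_monotone_in_count(self):
        m = make_map([[0, 2, 8], [2, 0, 5], [8, 5, 0]])
        assert contact_to_distance(m, 0, 2) < contact_to_distance(m, 1, 2) < contact_to_distance(m, 0, 1)


class TestIntraSegmentDistance:
    def test_zero_gap_both_models(self):
        for model in ("interpolate_distance", "count_per_bp"):
            assert intra_segment_distance(0, 8, 40_000, 10, model) == 0

    def test_full_segment_reproduces_adjacent_distance(self):
        # b = r -> map_max + 1 - C, the distance of an average adjacent pair
        assert intra_segment_distance(40_000, 8, 40_000, 10) == 10 + 1 - 8

    def test_half_segment_hand_value(self):
        assert intra_segment_distance(20_000, 8, 40_000, 10) == 1.5

    def test_count_per_bp_literal_model(self):
        assert intra_segment_distance(20_000, 8, 40_000, 10, "count_per_bp") == 4.0

    def test_negative_gap_rejected(self):
        with pytest.raises(ValueError):
            intra_segment_distance(-1, 8, 40_000, 10)


def two_gene_genome(seg_gap_counts, r=40_000):
    """Two genes in adjacent segments of a 3-bin chromosome."""
    counts = np.zeros((3, 3))
    counts[0, 1] = counts[1, 0] = seg_gap_counts
    counts[1, 2] = counts[2, 1] = 10
    ann = GenomeAnnotation(
        name="g",
        genes=(
            Gene("gA", "chr1", 1_000, 3_000, "fA"),
            Gene("gB", "chr1", r + 1_000, r + 3_000, "fB"),
        ),
    )
    return ann, [make_map(counts, r=r)]


class TestBuildGraphs:
    def test_adjacent_max_count_edge_weight_one(self):
        ann, maps = two_gene_genome(10)
        fg = build_spatial_graph(ann, maps)
        assert fg.graph.weight("gA", "gB") == 1.0

    def test_adjacent_empty_cell_uses_estimator(self):
        ann, maps = two_gene_genome(0)
        fg = build_spatial_graph(ann, maps)
        # C = mean of non-empty adjacent cells = 10; max = 10; b = 40000
        assert fg.graph.weight("gA", "gB") == pytest.approx(1.0)

    def test_same_segment_chain(self):
        ann = GenomeAnnotation(
            name="g",
            genes=(
                Gene("gA", "chr1", 1_000, 3_000, "fA"),
                Gene("gB", "chr1", 11_000, 13_000, "fB"),
                Gene("gC", "chr1", 21_000, 23_000, "fC"),
            ),
        )
        maps = [make_map([[0, 8], [8, 0]])]
        fg = build_spatial_graph(ann, maps)
        # chained in midpoint order; no direct A-C edge
        w = intra_segment_distance(10_000, 8, 40_000, 8)
        assert fg.graph.weight("gA", "gB") == pytest.approx(w)
        assert fg.graph.weight("gB", "gC") == pytest.approx(w)
        assert fg.graph.weight("gA", "gC") is None

    def test_chromosomes_without_inter_map_stay_separate(self):
        ann = GenomeAnnotation(
            name="g",
            genes=(
                Gene("gA", "chr1", 1_000, 3_000, "fA"),
                Gene("gB", "chr2", 1_000, 3_000, "fB"),
            ),
        )
        maps = [
            make_map([[0, 5], [5, 0]], chrom="chr1"),
            make_map([[0, 5], [5, 0]], chrom="chr2"),
        ]
        fg = build_spatial_graph(ann, maps)
        assert fg.graph.weight("gA", "gB") is None

    def test_interchromosomal_map_connects(self):
        ann = GenomeAnnotation(
            name="g",
            genes=(
                Gene("gA", "chr1", 1_000, 3_000, "fA"),
                Gene("gB", "chr2", 1_000, 3_000, "fB"),
            ),
        )
        inter = HiCMap(
            chrom_a="chr1", chrom_b="chr2", resolution_bp=40_000,
            counts=np.array([[9.0, 0.0], [0.0, 0.0]]),
        )
        fg = build_spatial_graph(ann, [inter])
        assert fg.graph.weight("gA", "gB") == 1.0  # 9 + 1 - 9

    def test_gene_beyond_map_extent_isolated(self, caplog):
        ann = GenomeAnnotation(
            name="g",
            genes=(
                Gene("gA", "chr1", 1_000, 3_000, "fA"),
                Gene("gFar", "chr1", 10 * 40_000, 11 * 40_000, "fB"),
            ),
        )
        with caplog.at_level("WARNING"):
            fg = build_spatial_graph(ann, [make_map([[0, 5], [5, 0]])])
        assert fg.graph.weight("gA", "gFar") is None
        assert "beyond the map extent" in caplog.text

    def test_sequential_subset_of_spatial_with_identical_weights(self):
        from deltateams.synth_oracle import SyntheticSpec, gen_synthetic_hic

        corpus = gen_synthetic_hic(SyntheticSpec(seed=1))
        c = compute_scale([m for g in corpus.genomes for m in g.maps])
        for genome in corpus.genomes:
            norm = [normalize_map(m, c) for m in genome.maps]
            g3 = build_spatial_graph(genome.annotation, norm).graph
            g1 = build_sequential_graph(genome.annotation, norm).graph
            for u, v, w in g1.edges():
                assert g3.weight(u, v) == pytest.approx(w)

    def test_sequential_colinear_genome_is_a_path(self):
        ann = GenomeAnnotation(
            name="g",
            genes=tuple(
                Gene(f"g{i}", "chr1", i * 40_000 + 1_000, i * 40_000 + 3_000, f"f{i}")
                for i in range(4)
            ),
        )
        counts = np.zeros((4, 4))
        for i in range(3):
            counts[i, i + 1] = counts[i + 1, i] = 5
        counts[0, 3] = counts[3, 0] = 9  # 3D shortcut, must be ignored
        fg = build_sequential_graph(ann, [make_map(counts)])
        assert fg.graph.weight("g0", "g3") is None
        assert sorted((u, v) for u, v, _ in fg.graph.edges()) == [
            ("g0", "g1"), ("g1", "g2"), ("g2", "g3"),
        ]

    def test_sequential_teams_match_sequence_reference(self):
        # colinear pair: teams must equal classical sequence delta-teams,
        # computed by direct gap-splitting on the gene order
        ann = GenomeAnnotation(
            name="g",
            genes=tuple(
                Gene(f"g{i}", "chr1", i * 40_000 + 1_000, i * 40_000 + 3_000, f"f{i}")
                for i in range(6)
            ),
        )
        counts = np.zeros((6, 6))
        adjacent = [9, 2, 9, 9, 3]  # distances 1, 8, 1, 1, 7 at max 9
        for i, c in enumerate(adjacent):
            counts[i, i + 1] = counts[i + 1, i] = c
        fg = build_sequential_graph(ann, [make_map(counts)])
        teams = find_delta_teams_families([fg, fg], 5)
        got = sorted(tuple(sorted(t.vertex_sets[0])) for t in teams)
        # reference: split the order wherever the adjacent distance > delta
        distances = [9 + 1 - c for c in adjacent]
        blocks, cur = [], ["g0"]
        for i, d in enumerate(distances):
            if d <= 5:
                cur.append(f"g{i+1}")
            else:
                blocks.append(tuple(cur))
                cur = [f"g{i+1}"]
        blocks.append(tuple(cur))
        assert got == sorted(blocks)


class TestSpatialGain:
    def team(self, genes, delta=3.0):
        return FamilyTeam(
            vertex_sets=(frozenset(genes), frozenset(genes)),
            family_spectrum=frozenset(genes),
            delta=delta,
        )

    def test_identical_reports_zero_gain(self):
        t = [self.team({"a", "b", "c"})]
        assert spatial_gain(t, t) == 0.0

    def test_fully_novel_team(self):
        t3 = [self.team({"a", "b", "c", "d", "e"})]
        assert spatial_gain(t3, []) == 5.0

    def test_two_gene_shortcut_fixture(self):
        t3 = [self.team({"a", "b", "x", "y"})]
        t1 = [self.team({"a", "b"})]
        assert spatial_gain(t3, t1) == 2.0

    def test_singleton_1d_teams_do_not_cover(self):
        t3 = [self.team({"a", "b"})]
        t1 = [
            FamilyTeam((frozenset({"a"}), frozenset({"a"})), frozenset({"a"}), 3.0),
            FamilyTeam((frozenset({"b"}), frozenset({"b"})), frozenset({"b"}), 3.0),
        ]
        assert spatial_gain(t3, t1) == 2.0

    def test_empty_3d_report(self):
        assert spatial_gain([], [self.team({"a"})]) == 0.0

    def test_singleton_3d_teams_ignored(self):
        t3 = [self.team({"a", "b"}), self.team({"z"})]
        assert spatial_gain(t3, t3) == 0.0
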