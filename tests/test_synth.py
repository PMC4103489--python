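"""Generator contracts: determinism, exact planted structure, truth tables."""

import pytest

from enrichmap.build import build_map, filter_enrichments
from enrichmap.model import BuildParameters, DataSet
from enrichmap.similarity import jaccard, overlap
from enrichmap.synth import (
    ClusterSpec,
    make_demo,
    synth_enrichments,
    synth_expression_bundle,
    synth_genesets,
    synth_gsea_bundle,
)
from enrichmap import io as emio


class TestSynthGenesets:
    def test_target_jaccard_achieved_exactly(self):
        sets, truth = synth_genesets(
            1, n_sets=2, universe_size=100,
            cluster_spec=[ClusterSpec(n_sets=2, jaccard=1 / 3)],
        )
        a, b = sets
        assert jaccard(a.genes, b.genes) == truth.jaccard[(a.name, b.name)]
        assert jaccard(a.genes, b.genes) == pytest.approx(1 / 3)
        assert overlap(a.genes, b.genes) == truth.overlap[(a.name, b.name)]

    def test_between_cluster_similarity_is_zero(self):
        sets, truth = synth_genesets(
            2, n_sets=12, universe_size=2000,
            cluster_spec=[ClusterSpec(4, 0.5), ClusterSpec(4, 0.25),
                          ClusterSpec(4, 0.75)],
        )
        by_cluster = {}
        for gs in sets:
            by_cluster.setdefault(gs.description, []).append(gs)
        clusters = list(by_cluster.values())
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                for a in clusters[i]:
                    for b in clusters[j]:
                        assert not (a.genes & b.genes)
                        assert truth.expected(a.name, b.name, "JACCARD") == 0.0

    def test_fixed_seed_gives_byte_identical_gmt(self, tmp_path):
        for name in ("a.gmt", "b.gmt"):
            synth_genesets(
                9, n_sets=5, universe_size=300,
                cluster_spec=[ClusterSpec(3, 0.5)],
                path=tmp_path / name,
            )
        assert (tmp_path / "a.gmt").read_bytes() == (tmp_path / "b.gmt").read_bytes()

    def test_infeasible_overlap_fraction_rejected(self):
        with pytest.raises(ValueError):
            ClusterSpec(n_sets=2, jaccard=1.5)

    def test_universe_too_small_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            synth_genesets(1, n_sets=50, universe_size=10,
                           cluster_spec=[ClusterSpec(50, 0.5, scale=10)])


class TestSynthEnrichments:
    def test_planted_fraction_passes_default_filters_exactly(self):
        sets, _ = synth_genesets(3, 10, 500, [ClusterSpec(10, 0.5)])
        results, truth = synth_enrichments(4, sets, frac_significant=0.5)
        kept = filter_enrichments(results, BuildParameters())
        assert len(kept) == 5
        assert {r.set_name for r in kept} == {
            n for n, t in truth.items() if t["significant"]
        }

    def test_zero_fraction_gives_empty_network_downstream(self):
        sets, _ = synth_genesets(3, 6, 300, [ClusterSpec(6, 0.5)])
        results, _ = synth_enrichments(4, sets, frac_significant=0.0)
        network, _ = build_map(DataSet.from_collections(sets, results))
        assert network.nodes == {}

    def test_direction_split_all_positive(self):
        sets, _ = synth_genesets(3, 8, 400, [ClusterSpec(8, 0.5)])
        results, truth = synth_enrichments(
            4, sets, frac_significant=1.0, direction_split=(1.0, 0.0)
        )
        assert all(r.direction == "pos" for r in results)

    def test_written_file_round_trips_through_generic_reader(self, tmp_path):
        sets, _ = synth_genesets(3, 6, 300, [ClusterSpec(6, 0.5)])
        results, _ = synth_enrichments(4, sets, frac_significant=0.5,
                                       path=tmp_path / "enr.txt")
        back = emio.read_generic_enrichments(tmp_path / "enr.txt")
        assert [r.set_name for r in back] == [r.set_name for r in results]
        for a, b in zip(back, results):
            assert a.pvalue == pytest.approx(b.pvalue, rel=1e-4)
            assert a.direction == b.direction


class TestSynthExpression:
    def test_emitted_rnk_matches_recomputed_ranking(self, tmp_path):
        sets, _ = synth_genesets(5, 6, 300, [ClusterSpec(6, 0.5)])
        expr, ranks, classes = synth_expression_bundle(
            6, sets, significant={sets[0].name}, outdir=tmp_path / "x"
        )
        back = emio.read_rank_file(tmp_path / "x" / "ranks.rnk")
        assert back.gene_ids == ranks.gene_ids
        cls = emio.read_class_file(tmp_path / "x" / "classes.cls")
        assert cls.class_names == ["classA", "classB"]
        m = emio.read_expression_matrix(tmp_path / "x" / "expression.txt")
        assert m.values.shape == expr.values.shape

    def test_fixed_seed_reproduces_files(self, tmp_path):
        sets, _ = synth_genesets(5, 4, 200, [ClusterSpec(4, 0.5)])
        for d in ("r1", "r2"):
            synth_expression_bundle(6, sets, significant=set(),
                                    outdir=tmp_path / d)
        for f in ("expression.txt", "ranks.rnk", "classes.cls"):
            assert (tmp_path / "r1" / f).read_bytes() == (
                tmp_path / "r2" / f
            ).read_bytes()

    def test_too_few_samples_rejected(self):
        sets, _ = synth_genesets(5, 4, 200, [ClusterSpec(4, 0.5)])
        with pytest.raises(ValueError):
            synth_expression_bundle(6, sets, significant=set(),
                                    n_samples_per_class=1)


class TestSynthGseaBundle:
    def test_written_records_parse_back(self, tmp_path):
        truth = synth_gsea_bundle(7, tmp_path / "edb", n_sets=3)
        bundle = emio.read_edb_directory(tmp_path / "edb")
        assert len(bundle.results) == 3
        assert {g.name for g in bundle.gene_sets} == set(truth["sets"])

    def test_infeasible_windows_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            synth_gsea_bundle(7, tmp_path / "edb", rank_at_max=60,
                              universe_size=100)


def test_make_demo_materializes_buildable_inputs(tmp_path):
    truth = make_demo(17, tmp_path / "demo")
    genesets = emio.read_gmt(tmp_path / "demo" / "genesets.gmt")
    results = emio.read_generic_enrichments(tmp_path / "demo" / "enrichments.txt")
    ds = DataSet.from_collections(genesets, results)
    network, report = build_map(ds)
    expected_nodes = {
        n for n, t in truth["enrichments"].items() if t["significant"]
    }
    assert set(network.nodes) == expected_nodes
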