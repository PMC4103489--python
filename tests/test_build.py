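"""Build-pipeline contracts: filtering, merging, refilter equivalence."""

import pytest

from enrichmap.build import (
    apply_universe_filter,
    assign_phenotype,
    build_map,
    filter_enrichments,
    refilter,
)
from enrichmap.model import (
    BuildParameters,
    DataSet,
    EnrichmentResult,
    GeneSet,
)
from enrichmap.synth import ClusterSpec, synth_enrichments, synth_genesets


def _result(name, p, q=None, **kw):
    return EnrichmentResult(set_name=name, pvalue=p, qvalue=q, **kw)


class TestFilterEnrichments:
    def test_default_cutoffs_keep_and_drop(self):
        params = BuildParameters()
        kept = filter_enrichments(
            [_result("A", 0.04, 0.09), _result("B", 0.06, 0.01),
             _result("C", 0.04, 0.2)],
            params,
        )
        assert [r.set_name for r in kept] == ["A"]

    def test_missing_q_filters_on_p_alone(self):
        kept = filter_enrichments([_result("A", 0.01)], BuildParameters())
        assert len(kept) == 1

    def test_boundaries_are_inclusive(self):
        kept = filter_enrichments([_result("A", 0.05, 0.1)], BuildParameters())
        assert len(kept) == 1


class TestUniverseFilter:
    SETS = {"S": GeneSet.from_genes("S", "", ["G1", "GX"])}

    def test_absent_universe_is_identity(self):
        assert apply_universe_filter(self.SETS, None) == self.SETS

    def test_sets_intersected_with_universe(self):
        out = apply_universe_filter(self.SETS, frozenset({"G1"}))
        assert out["S"].genes == frozenset({"G1"})

    def test_fully_outside_set_dropped_with_warning(self):
        from enrichmap.build import BuildReport

        report = BuildReport()
        out = apply_universe_filter(self.SETS, frozenset({"ZZZ"}), report)
        assert out == {}
        assert report.emptied_by_universe[1] == 1
        assert any("dropped" in w for w in report.warnings)


class TestAssignPhenotype:
    DS = DataSet(genesets={}, enrichments=[], phenotype1="heart", phenotype2="tail")

    def test_positive_nes_maps_to_first_phenotype(self):
        r = _result("A", 0.01, nes=2.1, direction="pos", source_dialect="gsea")
        assert assign_phenotype(r, self.DS) == ("heart", False)

    def test_negative_nes_maps_to_second_phenotype(self):
        r = _result("A", 0.01, nes=-1.7, direction="neg", source_dialect="gsea")
        assert assign_phenotype(r, self.DS) == ("tail", False)

    def test_unsigned_maps_to_first_phenotype_with_neutral_flag(self):
        assert assign_phenotype(_result("A", 0.01), self.DS) == ("heart", True)


class TestBuildMap:
    def test_micro_fixture_yields_three_nodes_two_edges(self, micro_ds):
        network, report = build_map(micro_ds)
        assert sorted(network.nodes) == ["SETA", "SETB", "SETC"]
        edges = {(e.set_a, e.set_b): e for e in network.edges}
        assert set(edges) == {("SETA", "SETB"), ("SETA", "SETC")}
        assert edges[("SETA", "SETB")].similarity == 0.5
        assert edges[("SETA", "SETB")].overlap_genes == frozenset({"G3", "G4"})
        assert edges[("SETA", "SETC")].similarity == 1.0
        assert report.nodes_total == 3
        assert report.kept_edges == 2

    def test_same_dataset_twice_is_idempotent_with_dual_membership(self, micro_ds):
        single, _ = build_map(micro_ds)
        double, _ = build_map([micro_ds, micro_ds])
        assert sorted(double.nodes) == sorted(single.nodes)
        for node in double.nodes.values():
            assert node.dataset_membership == frozenset({1, 2})
            assert node.pvalue[1] == node.pvalue[2]
        assert [(e.set_a, e.set_b, e.similarity) for e in double.edges] == [
            (e.set_a, e.set_b, e.similarity) for e in single.edges
        ]

    def test_all_insignificant_gives_empty_network_with_warning(self):
        ds = DataSet.from_collections(
            [GeneSet.from_genes("S", "", ["G1"])], [_result("S", 1.0)]
        )
        network, report = build_map(ds)
        assert network.nodes == {}
        assert network.edges == []
        assert any("empty" in w for w in report.warnings)

    def test_more_than_two_datasets_rejected(self, micro_ds):
        with pytest.raises(ValueError, match="2 datasets"):
            build_map([micro_ds, micro_ds, micro_ds])

    def test_unresolved_significant_set_warned_not_silently_dropped(self, micro_ds):
        micro_ds.enrichments.append(_result("GHOST", 0.001, 0.001))
        network, report = build_map(micro_ds)
        assert "GHOST" not in network.nodes
        assert any("GHOST" in w for w in report.warnings)

    def test_report_counts_reconcile(self, micro_ds):
        micro_ds.enrichments.append(_result("GHOST", 0.001, 0.001))
        _, report = build_map(micro_ds)
        assert report.nodes_per_dataset[1] == (
            report.enrichments_significant[1]
            - report.unresolved[1]
            - report.emptied_by_universe.get(1, 0)
        )

    def test_universe_filter_shrinks_node_gene_sets(self, micro_ds):
        from enrichmap.model import ExpressionMatrix
        import pandas as pd

        genes = ["G1", "G2", "G3", "G4", "G5"]  # G6 missing
        micro_ds.expression = ExpressionMatrix(
            gene_ids=genes,
            gene_descriptions=[""] * 5,
            sample_names=["s1", "s2"],
            values=pd.DataFrame([[0.0, 1.0]] * 5, index=genes,
                                columns=["s1", "s2"]),
        )
        network, _ = build_map(micro_ds)
        assert network.nodes["SETB"].genes == frozenset({"G3", "G4", "G5"})
        assert network.nodes["SETB"].size == 3


def _hundred_set_dataset(seed=5):
    genesets, _ = synth_genesets(
        seed,
        n_sets=100,
        universe_size=6000,
        cluster_spec=[
            ClusterSpec(n_sets=30, jaccard=0.5, scale=3),
            ClusterSpec(n_sets=30, jaccard=0.25, scale=2),
            ClusterSpec(n_sets=20, jaccard=0.6, scale=4),
        ],
    )
    results, _ = synth_enrichments(seed + 1, genesets, frac_significant=0.7)
    return DataSet.from_collections(genesets, results)


class TestMonotonicityAndRefilter:
    def test_stricter_cutoffs_give_node_and_edge_subsets(self):
        ds = _hundred_set_dataset()
        loose, _ = build_map(ds, BuildParameters(pvalue_cutoff=0.05,
                                                 qvalue_cutoff=0.1,
                                                 similarity_cutoff=0.25))
        for p, q, s in [(0.03, 0.1, 0.25), (0.05, 0.05, 0.25), (0.05, 0.1, 0.5)]:
            tight, _ = build_map(
                ds, BuildParameters(pvalue_cutoff=p, qvalue_cutoff=q,
                                    similarity_cutoff=s)
            )
            assert set(tight.nodes) <= set(loose.nodes)
            assert {(e.set_a, e.set_b) for e in tight.edges} <= {
                (e.set_a, e.set_b) for e in loose.edges
            }

    def test_tightening_similarity_only_keeps_node_set(self):
        ds = _hundred_set_dataset()
        base, _ = build_map(ds, BuildParameters(similarity_cutoff=0.2))
        tighter = refilter(base, base.parameters.with_(similarity_cutoff=0.6))
        assert set(tighter.nodes) == set(base.nodes)
        assert {(e.set_a, e.set_b) for e in tighter.edges} <= {
            (e.set_a, e.set_b) for e in base.edges
        }

    @pytest.mark.parametrize(
        "new", [dict(pvalue_cutoff=0.01), dict(qvalue_cutoff=0.02),
                dict(similarity_cutoff=0.5),
                dict(pvalue_cutoff=0.03, qvalue_cutoff=0.05,
                     similarity_cutoff=0.75)]
    )
    def test_refilter_equals_rebuild(self, new):
        ds = _hundred_set_dataset()
        envelope = BuildParameters(similarity_cutoff=0.25)
        base, _ = build_map(ds, envelope)
        refiltered = refilter(base, envelope.with_(**new))
        rebuilt, _ = build_map(ds, envelope.with_(**new))
        assert set(refiltered.nodes) == set(rebuilt.nodes)
        assert [(e.set_a, e.set_b, e.similarity) for e in refiltered.edges] == [
            (e.set_a, e.set_b, e.similarity) for e in rebuilt.edges
        ]

    def test_identical_params_refilter_is_identity(self, micro_network):
        same = refilter(micro_network, micro_network.parameters)
        assert same.nodes == micro_network.nodes
        assert same.edges == micro_network.edges

    def test_loosening_beyond_envelope_is_error(self, micro_network):
        with pytest.raises(ValueError, match="loosen"):
            refilter(micro_network, micro_network.parameters.with_(pvalue_cutoff=0.5))
        with pytest.raises(ValueError, match="loosen"):
            refilter(
                micro_network,
                micro_network.parameters.with_(similarity_cutoff=0.1),
            )
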