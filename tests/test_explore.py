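"""Search, heatmap slices and leading-edge extraction."""

import pandas as pd
import pytest

from enrichmap.explore import leading_edge_genes, search_nodes, selection_heatmap
from enrichmap.model import (
    DataSet,
    EnrichmentResult,
    ExpressionMatrix,
    RankedList,
)
from enrichmap.synth import synth_gsea_bundle
from enrichmap import io as emio


class TestSearch:
    def test_member_gene_returns_every_containing_set(self, micro_network):
        # G3 is shared by SETA and SETB only
        assert search_nodes(micro_network, "G3") == ["SETA", "SETB"]
        assert search_nodes(micro_network, "g3") == ["SETA", "SETB"]

    def test_set_name_returns_that_node(self, micro_network):
        assert search_nodes(micro_network, "SETC") == ["SETC"]

    def test_no_occurrence_returns_empty(self, micro_network):
        assert search_nodes(micro_network, "XYZZY") == []

    def test_search_is_reflexive_over_all_nodes(self, micro_network):
        for name in micro_network.node_names:
            assert name in search_nodes(micro_network, name)

    def test_empty_query_rejected(self, micro_network):
        with pytest.raises(ValueError):
            search_nodes(micro_network, "")


def _expression_ds(micro_ds):
    genes = ["G1", "G2", "G3", "G4", "G5", "G6"]
    micro_ds.expression = ExpressionMatrix(
        gene_ids=genes,
        gene_descriptions=[""] * 6,
        sample_names=["s1", "s2"],
        values=pd.DataFrame(
            [[float(i), float(i) + 1] for i in range(6)],
            index=genes, columns=["s1", "s2"],
        ),
    )
    return micro_ds


class TestSelectionHeatmap:
    def test_single_node_rows_are_node_genes(self, micro_ds, micro_network):
        ds = _expression_ds(micro_ds)
        s = selection_heatmap(micro_network, ["SETA"], ds)
        assert sorted(s.gene_ids) == ["G1", "G2", "G3", "G4"]

    def test_edge_contributes_its_overlap_genes(self, micro_ds, micro_network):
        ds = _expression_ds(micro_ds)
        edge = next(e for e in micro_network.edges
                    if (e.set_a, e.set_b) == ("SETA", "SETB"))
        s = selection_heatmap(micro_network, [edge], ds)
        assert sorted(s.gene_ids) == ["G3", "G4"]

    def test_intersection_of_disjoint_nodes_is_valid_empty_slice(
        self, micro_ds, micro_network
    ):
        ds = _expression_ds(micro_ds)
        s = selection_heatmap(micro_network, ["SETB", "SETC"], ds,
                              mode="intersection")
        assert s.gene_ids == []
        assert s.expression.empty

    def test_union_over_all_nodes_covers_every_network_gene(
        self, micro_ds, micro_network
    ):
        ds = _expression_ds(micro_ds)
        s = selection_heatmap(micro_network, list(micro_network.node_names), ds)
        all_genes = set().union(*(n.genes for n in micro_network.nodes.values()))
        assert set(s.gene_ids) == all_genes & set(ds.expression.gene_ids)

    def test_row_order_follows_ranks_when_present(self, micro_ds, micro_network):
        ds = _expression_ds(micro_ds)
        ds.ranks = RankedList(gene_ids=["G4", "G3", "G1", "G2", "G5", "G6"],
                              scores=[6.0, 5.0, 4.0, 3.0, 2.0, 1.0])
        s = selection_heatmap(micro_network, ["SETA"], ds)
        assert s.gene_ids == ["G4", "G3", "G1", "G2"]

    def test_missing_expression_is_error(self, micro_ds, micro_network):
        with pytest.raises(ValueError, match="expression"):
            selection_heatmap(micro_network, ["SETA"], micro_ds)

    def test_tsv_export_has_leading_edge_column(self, micro_ds, micro_network,
                                                tmp_path):
        ds = _expression_ds(micro_ds)
        s = selection_heatmap(micro_network, ["SETC"], ds,
                              leading_edge=["G1"])
        out = tmp_path / "slice.tsv"
        s.to_tsv(out)
        lines = out.read_text().strip().split("\n")
        assert lines[0].split("\t")[:2] == ["gene", "leading_edge"]
        flags = {l.split("\t")[0]: l.split("\t")[1] for l in lines[1:]}
        assert flags == {"G1": "yes", "G2": "no"}


def brute_force_leading_edge(members, ranks: RankedList, k: int, direction: str):
    """Oracle: scan every member's 1-based rank position directly."""
    n = len(ranks)
    out = set()
    for g in members:
        pos = ranks.position(g)
        if pos is None:
            continue
        if direction == "neg":
            if pos > n - min(k, n):
                out.add(g)
        else:
            if pos <= k:
                out.add(g)
    return out


class TestLeadingEdge:
    RANKS = RankedList(gene_ids=["A", "B", "D", "C"], scores=[4.0, 3.0, 2.0, 1.0])

    def _result(self, k, direction="pos"):
        nes = 2.0 if direction == "pos" else -2.0
        return EnrichmentResult(set_name="S", pvalue=0.01, nes=nes,
                                direction=direction, rank_at_max=k,
                                source_dialect="gsea")

    def test_positive_prefix_rule(self):
        got = leading_edge_genes(self._result(2), {"A", "B", "C"}, self.RANKS)
        assert got == frozenset({"A", "B"})
        assert got == brute_force_leading_edge({"A", "B", "C"}, self.RANKS, 2, "pos")

    def test_negative_suffix_rule(self):
        got = leading_edge_genes(self._result(2, "neg"), {"A", "D", "C"}, self.RANKS)
        assert got == frozenset({"D", "C"})
        assert got == brute_force_leading_edge({"A", "D", "C"}, self.RANKS, 2, "neg")

    def test_full_length_window_returns_entire_member_set(self):
        members = {"A", "B", "C"}
        assert leading_edge_genes(self._result(4), members, self.RANKS) == members

    def test_monotone_in_rank_at_max(self):
        members = {"A", "B", "D", "C"}
        previous = frozenset()
        for k in range(5):
            current = leading_edge_genes(self._result(k), members, self.RANKS)
            assert previous <= current <= frozenset(members)
            previous = current

    def test_non_gsea_record_rejected(self):
        r = EnrichmentResult(set_name="S", pvalue=0.01, source_dialect="generic")
        with pytest.raises(ValueError, match="GSEA"):
            leading_edge_genes(r, {"A"}, self.RANKS)

    def test_missing_rank_at_max_names_requirement(self):
        r = EnrichmentResult(set_name="S", pvalue=0.01, nes=1.0, direction="pos",
                             source_dialect="gsea")
        with pytest.raises(ValueError, match="rank_at_max"):
            leading_edge_genes(r, {"A"}, self.RANKS)

    def test_planted_bundle_leading_edges_recovered_exactly(self, tmp_path):
        truth = synth_gsea_bundle(23, tmp_path / "edb", n_sets=6,
                                  members_leading=4, members_rest=5,
                                  rank_at_max=25, universe_size=120)
        bundle = emio.read_edb_directory(tmp_path / "edb")
        sets = {g.name: g.genes for g in bundle.gene_sets}
        assert len(bundle.results) == 6
        for r in bundle.results:
            got = leading_edge_genes(r, sets[r.set_name], bundle.ranks)
            assert sorted(got) == truth["sets"][r.set_name]["leading_edge"]
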