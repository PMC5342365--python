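"""Pathway data model, TSV dialect, KGML reader and endpoint marking."""
import logging

import networkx as nx
import numpy as np
import pytest

from mirpact import (
    EdgeClass,
    NodeClass,
    PathwayEdge,
    PathwayGraph,
    PathwayNode,
    PathwayParseError,
    PathwayValidationError,
    mark_endpoints,
    read_pathway_kgml,
    read_pathway_tsv,
    write_pathway_tsv,
)

from conftest import build_graph

TSV_BASIC = """\
#! pathway_id: path:demo
#! name: demo pathway
#node\tgene:A\tgene\t0
#node\tgene:B\tgene\t0
#node\tgene:C\tgene\t1
source\ttarget\tweight\tedge_class
gene:A\tgene:B\t1\tgene_gene
gene:B\tgene:C\t-1\tgene_gene
"""


class TestPathwayTsv:
    def test_basic_parse(self, tmp_path):
        f = tmp_path / "demo.tsv"
        f.write_text(TSV_BASIC)
        g = read_pathway_tsv(f)
        assert g.pathway_id == "path:demo"
        assert g.name == "demo pathway"
        assert set(g.nodes) == {"gene:A", "gene:B", "gene:C"}
        assert len(g.edges) == 2
        assert g.effective_beta()[("gene:B", "gene:C")] == -1.0
        assert g.endpoints == {"gene:C"}

    def test_zero_weight_edge_dropped_with_warning(self, tmp_path, caplog):
        f = tmp_path / "z.tsv"
        f.write_text(
            "#node\tgene:A\tgene\t0\n#node\tgene:B\tgene\t0\n"
            "source\ttarget\tweight\tedge_class\n"
            "gene:A\tgene:B\t0\tgene_gene\n"
        )
        with caplog.at_level(logging.WARNING):
            g = read_pathway_tsv(f)
        assert len(g.edges) == 0
        assert any("zero-weight" in rec.message for rec in caplog.records)

    def test_dangling_edge_is_validation_error(self, tmp_path):
        f = tmp_path / "d.tsv"
        f.write_text(
            "#node\tgene:A\tgene\t0\n"
            "source\ttarget\tweight\tedge_class\n"
            "gene:A\tgene:D\t1\tgene_gene\n"
        )
        with pytest.raises(PathwayValidationError, match="gene:D"):
            read_pathway_tsv(f)

    @pytest.mark.parametrize(
        "bad_line",
        ["gene:A\tgene:B\tnot_a_number\tgene_gene", "gene:A\tgene:B\t1\tbogus_class",
         "gene:A\tgene:B\t1"],
    )
    def test_malformed_row_names_line_number(self, tmp_path, bad_line):
        f = tmp_path / "m.tsv"
        f.write_text(
            "#node\tgene:A\tgene\t0\n#node\tgene:B\tgene\t0\n"
            "source\ttarget\tweight\tedge_class\n" + bad_line + "\n"
        )
        with pytest.raises(PathwayParseError, match=":4:"):
            read_pathway_tsv(f)

    def test_write_read_roundtrip_is_canonical(self, tmp_path):
        g = build_graph(
            "path:rt",
            [("gene:A", NodeClass.GENE), ("mirna:m1", NodeClass.MIRNA), "gene:B"],
            [
                ("gene:A", "gene:B", 1.0),
                ("mirna:m1", "gene:B", -1.0, EdgeClass.MIRNA_INHIBITION),
            ],
        )
        f1 = tmp_path / "a.tsv"
        f2 = tmp_path / "b.tsv"
        write_pathway_tsv(g, f1)
        g2 = read_pathway_tsv(f1)
        write_pathway_tsv(g2, f2)
        assert f1.read_text() == f2.read_text()
        assert set(g2.nodes) == set(g.nodes)
        assert sorted((e.source, e.target, e.weight) for e in g2.edges) == sorted(
            (e.source, e.target, e.weight) for e in g.edges
        )


KGML_MINIMAL = """<?xml version="1.0"?>
<pathway name="path:test01" org="hsa" number="01" title="Tiny pathway">
  <entry id="1" name="hsa:10" type="gene"/>
  <entry id="2" name="hsa:20" type="gene"/>
  <relation entry1="1" entry2="2" type="PPrel">
    <subtype name="activation" value="--&gt;"/>
  </relation>
</pathway>
"""

KGML_BINDING = KGML_MINIMAL.replace('name="activation"', 'name="binding/association"')

KGML_GROUP = """<?xml version="1.0"?>
<pathway name="path:test02" org="hsa" number="02" title="Grouped">
  <entry id="1" name="hsa:10" type="gene"/>
  <entry id="2" name="hsa:20" type="gene"/>
  <entry id="3" type="group">
    <component id="1"/>
    <component id="2"/>
  </entry>
  <entry id="4" name="hsa:40" type="gene"/>
  <entry id="5" name="path:hsa00000" type="map"/>
  <relation entry1="4" entry2="3" type="PPrel">
    <subtype name="activation" value="--&gt;"/>
  </relation>
</pathway>
"""


class TestKgml:
    def test_minimal_activation(self, tmp_path):
        f = tmp_path / "t.xml"
        f.write_text(KGML_MINIMAL)
        g = read_pathway_kgml(f)
        assert g.pathway_id == "path:test01"
        assert set(g.nodes) == {"hsa:10", "hsa:20"}
        assert len(g.edges) == 1
        assert g.edges[0].weight == 1.0

    def test_unmapped_subtype_is_pruned(self, tmp_path):
        f = tmp_path / "b.xml"
        f.write_text(KGML_BINDING)
        g = read_pathway_kgml(f)
        assert len(g.edges) == 0

    def test_group_expands_to_members(self, tmp_path):
        f = tmp_path / "g.xml"
        f.write_text(KGML_GROUP)
        g = read_pathway_kgml(f)
        eff = g.effective_beta()
        assert eff[("hsa:40", "hsa:10")] == 1.0
        assert eff[("hsa:40", "hsa:20")] == 1.0
        assert len(g.edges) == 2

    def test_custom_beta_table(self, tmp_path):
        f = tmp_path / "t.xml"
        f.write_text(KGML_MINIMAL.replace("activation", "phosphorylation"))
        g = read_pathway_kgml(f, beta_table={"phosphorylation": 0.5})
        assert g.effective_beta()[("hsa:10", "hsa:20")] == 0.5

    def test_malformed_xml(self, tmp_path):
        f = tmp_path / "bad.xml"
        f.write_text("<pathway><entry id=")
        with pytest.raises(PathwayParseError):
            read_pathway_kgml(f)


class TestEndpoints:
    def test_chain_sink(self):
        g = build_graph(
            "p", ["gene:A", "gene:B", "gene:C"],
            [("gene:A", "gene:B", 1.0), ("gene:B", "gene:C", 1.0)],
        )
        assert g.endpoints == {"gene:C"}

    def test_cycle_has_no_endpoints(self, caplog):
        g = build_graph(
            "p", ["gene:A", "gene:B"],
            [("gene:A", "gene:B", 1.0), ("gene:B", "gene:A", 1.0)],
            auto_endpoints=False,
        )
        with caplog.at_level(logging.WARNING):
            g = mark_endpoints(g)
        assert g.endpoints == set()
        assert any("no sink" in rec.message for rec in caplog.records)

    def test_curated_overrides_sinks(self):
        g = build_graph(
            "p", ["gene:A", "gene:B", "gene:C"],
            [("gene:A", "gene:B", 1.0), ("gene:B", "gene:C", 1.0)],
            auto_endpoints=False,
        )
        g = mark_endpoints(g, curated={"gene:B"})
        assert g.endpoints == {"gene:B"}

    def test_curated_unknown_id_ignored_with_warning(self, caplog):
        g = build_graph("p", ["gene:A"], [], auto_endpoints=False)
        with caplog.at_level(logging.WARNING):
            g = mark_endpoints(g, curated={"gene:A", "gene:Z"})
        assert g.endpoints == {"gene:A"}
        assert any("gene:Z" in rec.message for rec in caplog.records)

    def test_input_graph_unmodified(self):
        g = build_graph("p", ["gene:A", "gene:B"], [("gene:A", "gene:B", 1.0)],
                        auto_endpoints=False)
        mark_endpoints(g)
        assert g.endpoints == set()

    def test_sinks_match_reachability_bruteforce(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(2, 21))
            ids = [f"gene:n{i}" for i in range(n)]
            edges = []
            for i in range(n):
                for j in range(n):
                    if i != j and rng.random() < 0.15:
                        edges.append((ids[i], ids[j], 1.0))
            g = build_graph("p", ids, edges)
            nxg = g.to_networkx()
            brute = {
                nid for nid in ids
                if not nx.descendants(nxg, nid)
                and g.nodes[nid].node_class is not NodeClass.MIRNA
            }
            # A sink cannot reach anything; a node with successors can.
            assert {
                nid for nid in g.endpoints
            } == {nid for nid in brute if nxg.out_degree(nid) == 0}
            assert g.endpoints == {nid for nid in ids if nxg.out_degree(nid) == 0}

    def test_upstream_downstream_symmetry(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            n = int(rng.integers(2, 15))
            ids = [f"gene:n{i}" for i in range(n)]
            edges = [
                (ids[i], ids[j], 1.0)
                for i in range(n)
                for j in range(n)
                if i != j and rng.random() < 0.2
            ]
            g = build_graph("p", ids, edges)
            for nid in ids:
                for u in g.upstream(nid):
                    assert nid in g.downstream(u)
                for d in g.downstream(nid):
                    assert nid in g.upstream(d)


class TestModelInvariants:
    def test_duplicate_node_rejected(self):
        with pytest.raises(PathwayValidationError, match="duplicate"):
            PathwayGraph.build("p", [PathwayNode("gene:A"), PathwayNode("gene:A")], [])

    def test_mirna_inhibition_weight_sign_enforced(self):
        with pytest.raises(PathwayValidationError):
            PathwayEdge("mirna:m", "gene:A", 1.0, EdgeClass.MIRNA_INHIBITION)
        with pytest.raises(PathwayValidationError):
            PathwayEdge("gene:A", "mirna:m", -1.0, EdgeClass.TF_ACTIVATION)

    def test_parallel_edges_sum_into_effective_beta(self):
        g = build_graph(
            "p", ["gene:A", "gene:B"],
            [("gene:A", "gene:B", 1.0), ("gene:A", "gene:B", 1.0)],
        )
        assert g.effective_beta()[("gene:A", "gene:B")] == 2.0
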