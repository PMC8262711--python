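"""Network assembly, variant mapping, caps, toggles and exports."""

import json

import networkx as nx
import pytest

from mechnet import annotations_io as aio
from mechnet.annotations_io import (DomainHit, Evidence, PPIRecord, PTMSite,
                                    PredictedEdge, StructCatalogEntry,
                                    UniProtFeature, VariantRecord)
from mechnet.ddi_stats import DomainPairStats
from mechnet.dmi_rules import DMIDecision
from mechnet.motif_scan import MotifInstance
from mechnet.network_build import (NetworkConfig, build_network, enforce_cap,
                                   expand_interactors, export_graph,
                                   filter_cancer_variants, map_variants)
from tests.conftest import make_protein


def ppi(a, b, n=2):
    return PPIRecord(pair=(a, b),
                     evidence=[Evidence(f"s{a}{b}{i}", "m", "low")
                               for i in range(n)])


class TestExpandInteractors:
    PPIS = [ppi("Q1", "A", 3), ppi("Q1", "B", 1), ppi("Q1", "C", 2),
            ppi("Q2", "A", 1), ppi("Q2", "D", 1)]

    def test_k_zero_identity(self):
        assert expand_interactors({"Q1"}, self.PPIS, 0) == {"Q1"}

    def test_rank_by_evidence(self):
        out = expand_interactors({"Q1"}, self.PPIS, 2)
        assert out == {"Q1", "A", "C"}

    def test_shared_partner_added_once(self):
        out = expand_interactors({"Q1", "Q2"}, self.PPIS, 1)
        assert out == {"Q1", "Q2", "A"}


class TestEnforceCap:
    def test_truncation_above_cap(self):
        names = [f"P{i:02d}" for i in range(30)]
        retained, warning = enforce_cap(names, cap=20)
        assert retained == names[:20]
        assert warning is not None and "20" in warning

    def test_under_and_at_cap_untouched(self):
        five = [f"P{i}" for i in range(5)]
        assert enforce_cap(five, cap=20) == (five, None)
        twenty = [f"P{i}" for i in range(20)]
        retained, warning = enforce_cap(twenty, cap=20)
        assert retained == twenty and warning is None


class TestMapVariants:
    def test_cluster_hits_one_motif(self):
        """Variants at 617, 618 and 620 all report a motif spanning their
        region (WW-binding-motif-style overlap at a channel C-terminus)."""
        motif = MotifInstance("P1", "LIG_WW_1", 615, 623, "PPPAYAAAA",
                              "annotated")
        variants = [VariantRecord("P1", pos, "P", "L", "disease",
                                  disease_name="Liddle syndrome",
                                  source="uniprot")
                    for pos in (617, 618, 620)]
        mapped = map_variants(variants, [motif])
        assert all(feats == [motif] for _, feats in mapped)

    def test_variant_outside_everything(self):
        dom = DomainHit("P1", "PF1", "d", 10, 20, 1e-6)
        (pair,) = map_variants([VariantRecord("P1", 5, "A", "V")], [dom])
        assert pair[1] == []

    def test_boundary_positions_inclusive(self):
        dom = DomainHit("P1", "PF1", "d", 10, 20, 1e-6)
        mapped = map_variants(
            [VariantRecord("P1", 10, "A", "V"),
             VariantRecord("P1", 20, "A", "V"),
             VariantRecord("P1", 21, "A", "V")], [dom])
        assert [len(feats) for _, feats in mapped] == [1, 1, 0]

    def test_point_feature_requires_equality(self):
        site = PTMSite("P1", 15, "S", "phosphorylation", "psp")
        mapped = map_variants(
            [VariantRecord("P1", 15, "S", "F"),
             VariantRecord("P1", 16, "A", "V")], [site])
        assert [len(feats) for _, feats in mapped] == [1, 0]

    def test_other_protein_features_ignored(self):
        dom = DomainHit("P2", "PF1", "d", 1, 100, 1e-6)
        (pair,) = map_variants([VariantRecord("P1", 5, "A", "V")], [dom])
        assert pair[1] == []


class TestFilterCancerVariants:
    def test_five_sample_boundary(self):
        low = VariantRecord("P1", 3, "A", "V", "cancer", sample_count=4)
        at = VariantRecord("P1", 4, "A", "V", "cancer", sample_count=5)
        assert filter_cancer_variants([low, at]) == [at]

    def test_non_cancer_untouched(self):
        user = VariantRecord("P1", 3, "A", "V", "user")
        assert filter_cancer_variants([user]) == [user]

    def test_counts_one_to_ten(self):
        variants = [VariantRecord("P1", i, "A", "V", "cancer", sample_count=i)
                    for i in range(1, 11)]
        assert len(filter_cancer_variants(variants)) == 6

    def test_missing_sample_count_is_error(self):
        broken = VariantRecord("P1", 3, "A", "V", "user")
        object.__setattr__(broken, "category", "cancer")
        with pytest.raises(ValueError):
            filter_cancer_variants([broken])


def small_network(**config_kw):
    """Two proteins with one domain each, a struct-catalog DDI entry, a
    PPI, a motif and a curated-feature partner annotation."""
    p1 = make_protein("P00001", "GG" + "A" * 30 + "PPAY" + "A" * 30,
                      gene="GENE1")
    p2 = make_protein("P00002", "M" + "C" * 60, gene="GENE2")
    domains = [DomainHit("P00001", "PF_A", "dom-a", 5, 25, 1e-8),
               DomainHit("P00002", "PF_B", "dom-b", 10, 40, 1e-8)]
    motif = MotifInstance("P00001", "LIG_WW_PPXY", 33, 36, "PPAY", "annotated")
    ptm = PTMSite("P00002", 5, "C", "glycosylation", "src")
    feat = UniProtFeature("P00001", "region", 40, 60, "binds partner",
                          partner_gene="GENE2")
    variants = [VariantRecord("P00001", 34, "P", "L", "cancer", sample_count=9),
                VariantRecord("P00001", 35, "A", "V", "cancer", sample_count=2)]
    ppis = [ppi("P00001", "P00002", 3)]
    catalog = [StructCatalogEntry("ddi", "PF_A", "PF_B", 3),
               StructCatalogEntry("dmi", "PF_B", "LIG_WW_PPXY", 2)]
    stats = [DomainPairStats(("PF_A", "PF_B"), observed=6, expected=0.5,
                             score=2.5, enriched=True, p_value=0.2)]
    dmi = [(motif, domains[1], DMIDecision(True, ()))]
    pred = [PredictedEdge(("P00001", "P00002"), "2C1M", 4.2, 0.01)]
    return build_network(
        [p1, p2], domains, [motif], [ptm], [feat], variants, ppis,
        catalog, stats, dmi, pred, NetworkConfig(**config_kw))


class TestBuildNetwork:
    def test_all_layers_present(self):
        net = small_network()
        etypes = {e.etype for e in net.edges}
        assert etypes == {"ppi", "ddi_struct", "ddi_inferred", "dmi_elm",
                          "dmi_struct", "pred_3d", "region_assoc"}

    def test_struct_ddi_edge_weight_is_structure_count(self):
        net = small_network()
        (edge,) = [e for e in net.edges if e.etype == "ddi_struct"]
        assert edge.weight == 3.0
        ends = {net.node_index()[n].kind for n in edge.endpoints}
        assert ends == {"domain"}

    def test_ppi_weight_is_evidence_count(self):
        net = small_network()
        (edge,) = [e for e in net.edges if e.etype == "ppi"]
        assert edge.weight == 3.0

    def test_region_assoc_matches_partner_gene(self):
        net = small_network()
        (edge,) = [e for e in net.edges if e.etype == "region_assoc"]
        kinds = sorted(net.node_index()[n].kind for n in edge.endpoints)
        assert kinds == ["protein", "uniprot_feature"]

    def test_cancer_display_filter_applied(self):
        net = small_network()
        variant_nodes = [n for n in net.nodes if n.kind == "variant"]
        assert [n.label for n in variant_nodes] == ["P34L"]

    def test_single_protein_no_edges(self):
        p1 = make_protein("P00001", "MKTAYIAKQR")
        net = build_network([p1], [DomainHit("P00001", "PF_A", "a", 2, 8, 1e-6)])
        assert len(net.edges) == 0
        assert {n.kind for n in net.nodes} == {"protein", "domain"}

    def test_layer_toggles_only_remove_edges(self):
        full = small_network()
        for etype in {e.etype for e in full.edges}:
            toggled = small_network(layers={etype: False})
            assert {e.edge_id for e in toggled.edges} == \
                {e.edge_id for e in full.edges if e.etype != etype}

    def test_structural_soundness(self):
        net = small_network()
        idx = net.node_index()
        for e in net.edges:
            assert all(n in idx for n in e.endpoints)
        for n in net.nodes:
            if n.kind != "protein":
                owner = idx[n.protein]
                assert owner.start <= n.start <= n.end <= owner.end

    def test_inferred_ddi_requires_enrichment(self):
        p1 = make_protein("P00001", "A" * 50, gene="G1")
        p2 = make_protein("P00002", "A" * 50, gene="G2")
        domains = [DomainHit("P00001", "PF_A", "a", 1, 20, 1e-6),
                   DomainHit("P00002", "PF_B", "b", 1, 20, 1e-6)]
        stats = [DomainPairStats(("PF_A", "PF_B"), 6, 0.5, 2.5, False, 0.2)]
        net = build_network([p1, p2], domains, ddi_statistics=stats)
        assert [e for e in net.edges if e.etype == "ddi_inferred"] == []


class TestExports:
    def test_unknown_format_rejected(self):
        with pytest.raises(ValueError, match="format"):
            export_graph(small_network(), "dot")

    def test_empty_network_valid_documents(self):
        from mechnet.network_build import MechNetwork
        empty = MechNetwork()
        doc = json.loads(export_graph(empty, "cyjs"))
        assert doc["elements"] == {"nodes": [], "edges": []}
        g = nx.parse_graphml(export_graph(empty, "graphml"))
        assert len(g) == 0

    def test_cyjs_round_trip_lossless(self):
        net = small_network()
        doc = json.loads(export_graph(net, "cyjs"))
        nodes = {n["data"]["id"] for n in doc["elements"]["nodes"]}
        assert nodes == {n.node_id for n in net.nodes}
        by_id = {e["data"]["id"]: e["data"] for e in doc["elements"]["edges"]}
        assert set(by_id) == {e.edge_id for e in net.edges}
        for e in net.edges:
            data = by_id[e.edge_id]
            assert data["etype"] == e.etype
            assert data["weight"] == e.weight
            assert {data["source"], data["target"]} == set(e.endpoints)
            if e.p_value is not None:
                assert data["p_value"] == e.p_value

    def test_graphml_round_trip(self):
        net = small_network()
        g = nx.parse_graphml(export_graph(net, "graphml"))
        assert set(g.nodes) == {n.node_id for n in net.nodes}
        edge_ids = {d["edge_id"] for *_ , d in g.edges(data=True)}
        assert edge_ids == {e.edge_id for e in net.edges}

    def test_exports_are_deterministic(self):
        assert export_graph(small_network(), "cyjs") == \
            export_graph(small_network(), "cyjs")
        assert export_graph(small_network(), "graphml") == \
            export_graph(small_network(), "graphml")


class TestInteractionTable:
    def test_row_per_edge_and_round_trip(self, tmp_path):
        net = small_network()
        path = tmp_path / "table.tsv"
        aio.write_interaction_table(net, path)
        df = aio.read_interaction_table(path)
        assert len(df) == len(net.edges)
        nodes = net.node_index()
        by_type = {}
        for e in net.edges:
            a, b = (nodes[n] for n in e.endpoints)
            by_type[e.etype] = (a.protein, b.protein, e.weight, e.p_value)
        for _, row in df.iterrows():
            a_prot, b_prot, weight, p_value = by_type[row["edge_type"]]
            assert {row["protein_a"], row["protein_b"]} == {a_prot, b_prot}
            assert row["weight"] == weight
            if p_value is not None:
                assert row["p_value"] == p_value

    def test_empty_network_header_only(self, tmp_path):
        from mechnet.network_build import MechNetwork
        path = tmp_path / "table.tsv"
        aio.write_interaction_table(MechNetwork(), path)
        lines = path.read_text().splitlines()
        assert len(lines) == 1
        assert lines[0].split("\t") == list(aio.INTERACTION_TABLE_COLUMNS)
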