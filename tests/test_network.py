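"""COM graph construction, edge typing, distances and functional modules."""

import numpy as np
import pandas as pd
import pytest

from riboarch.components import ComponentAnnotation, ProteinComponent
from riboarch.contacts import read_structure, detect_interfaces
from riboarch.network import (FunctionalSites, assign_functional_modules,
                              build_graph, canonical_status_pair,
                              com_distances, contact_table,
                              graph_from_contact_table, to_graphml)
from riboarch.synthetic import ToyChain, make_toy_complex


def table(rows):
    recs = []
    for pa, ca, sa, pb, cb, sb, ct in rows:
        recs.append({"protein_a": pa, "component_a": ca, "status_a": sa,
                     "protein_b": pb, "component_b": cb, "status_b": sb,
                     "status_pair": canonical_status_pair(sa, sb),
                     "contact_type": ct})
    return pd.DataFrame(recs)


class TestStatusPairs:
    @pytest.mark.parametrize("a,b,expected", [
        ("B", "U", "U-B"), ("U", "B", "U-B"), ("A", "U", "U-A"),
        ("U", "Ub", "Ub-U"), ("Ub", "B", "Ub-B"), ("Ua", "Ua", "Ua-Ua"),
        ("E", "A", "A-E"), ("Ae", "E", "Ae-E"), ("funct", "B", "B-funct")])
    def test_canonical_ordering(self, a, b, expected):
        assert canonical_status_pair(a, b) == expected


@pytest.fixture(scope="module")
def triple(tmp_path_factory):
    out = tmp_path_factory.mktemp("triple")
    sep = 2 * (2.3 + 1.3) + 2 * 1.7 + 1.0   # touching neighbours
    toy = make_toy_complex(
        [ToyChain("A", 9), ToyChain("B", 9, (sep, 0, 0)),
         ToyChain("C", 9, (2 * sep, 0, 0))], out, name="triple")
    return read_structure(toy.pdb_path)


class TestBuildGraphFromStructure:
    def ann(self, kind="globular"):
        def c(pid, chain, kind, **kw):
            return ProteinComponent(pid, chain, kind, ranges=[(1, 9)], **kw)
        if kind == "globular":
            comps = [c("uL1", "A", "globular", status="U"),
                     c("uL2", "B", "globular", status="U"),
                     c("uL3", "C", "globular", status="U")]
        else:
            comps = [c("uL1", "A", "extension", category="segment",
                       terminus="N", status="inherited"),
                     c("uL2", "B", "extension", category="helix",
                       terminus="C", status="inherited"),
                     c("uL3", "C", "extension", category="loop",
                       terminus="internal", status="inherited")]
        return ComponentAnnotation("A", comps)

    def test_path_graph_of_three_chains(self, triple):
        contacts = detect_interfaces(triple)
        g = build_graph(contacts, self.ann(), FunctionalSites({}), triple)
        assert sorted(g.graph.nodes) == ["uL1", "uL2", "uL3"]
        assert sorted(map(sorted, g.graph.edges)) == [["uL1", "uL2"],
                                                      ["uL2", "uL3"]]

    def test_all_extension_sides_classified_ext_ext(self, triple):
        contacts = detect_interfaces(triple)
        g = build_graph(contacts, self.ann("extension"),
                        FunctionalSites({}), triple)
        assert all(d["contact_type"] == "ext_ext"
                   for _, _, d in g.graph.edges(data=True))

    def test_unannotated_chain_is_named_in_error(self, triple):
        contacts = detect_interfaces(triple)
        ann = ComponentAnnotation("A", [ProteinComponent(
            "uL1", "A", "globular", ranges=[(1, 9)], status="U")])
        with pytest.raises(ValueError, match="'B'|'C'"):
            build_graph(contacts, ann, FunctionalSites({}), triple)

    def test_functional_site_contact(self, triple):
        # chain C is rRNA; residues 1-9 define the PTC
        contacts = detect_interfaces(triple)
        comps = [ProteinComponent("uL1", "A", "globular", ranges=[(1, 9)],
                                  status="U"),
                 ProteinComponent("uL2", "B", "globular", ranges=[(1, 9)],
                                  status="U")]
        ann = ComponentAnnotation("A", comps, non_protein_chains={"C": "rRNA"})
        sites = FunctionalSites({"PTC": [("C", 1, 9)]})
        g = build_graph(contacts, ann, sites, triple)
        assert g.graph.has_edge("uL2", "PTC")
        assert g.graph.nodes["PTC"]["node_kind"] == "functional_site"
        assert g.graph.edges["uL2", "PTC"]["contact_type"] == "G_funct"


class TestAggregation:
    def test_multiplicity_counted_not_multiedged(self):
        t = table([
            ("uL1", "G", "U", "uL2", "G", "U", "G_G"),
            ("uL1", "ext:C-mix", "Ue", "uL2", "G", "U", "ext_G"),
            ("uL2", "G", "U", "uL3", "G", "U", "G_G")])
        g = graph_from_contact_table(t, "E")
        assert g.graph.number_of_edges() == 2
        assert g.graph.edges["uL1", "uL2"]["n_connections"] == 2
        assert g.graph.edges["uL2", "uL3"]["n_connections"] == 1

    def test_aggregation_idempotent(self):
        t = table([("uL1", "G", "U", "uL2", "G", "U", "G_G"),
                   ("uL1", "ext:N-loop", "Ue", "uL2", "G", "U", "ext_G")])
        g1 = graph_from_contact_table(t, "E")
        g2 = graph_from_contact_table(contact_table(g1), "E")
        assert set(g1.graph.edges) == set(g2.graph.edges)
        assert (g1.graph.edges["uL1", "uL2"]["n_connections"]
                == g2.graph.edges["uL1", "uL2"]["n_connections"])

    def test_degree_sum_is_twice_edge_count(self, kingdom_graphs):
        for g in kingdom_graphs.values():
            degs = sum(d for _, d in g.graph.degree())
            assert degs == 2 * g.graph.number_of_edges()

    def test_every_contact_has_exactly_one_type(self, kingdom_graphs):
        for g in kingdom_graphs.values():
            counts = pd.Series([c.contact_type for c in g.stats_contacts()]
                               ).value_counts()
            assert counts.sum() == len(g.stats_contacts())

    def test_planted_multiplicities_recovered(self, study, kingdom_graphs):
        for stage, expected in study.truth["multiplicities"].items():
            g = kingdom_graphs[stage].graph
            found = {" / ".join(sorted((u, v))): d["n_connections"]
                     for u, v, d in g.edges(data=True)
                     if d["n_connections"] > 1}
            assert found == expected


class TestDistances:
    def test_three_four_five(self):
        t = table([("a", "G", "U", "b", "G", "U", "G_G")])
        g = graph_from_contact_table(t, "B", coords={"a": np.zeros(3),
                                                     "b": np.array([3., 4., 0.])})
        df, summary = com_distances(g)
        assert df["com_distance"].iloc[0] == pytest.approx(5.0)
        assert summary["max"] == pytest.approx(5.0)

    def test_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(3)
        coords = {n: rng.normal(size=3) * 20 for n in "abcd"}
        t = table([("a", "G", "U", "b", "G", "U", "G_G"),
                   ("b", "G", "U", "c", "G", "U", "G_G"),
                   ("c", "G", "U", "d", "G", "U", "G_G")])
        _, s1 = com_distances(graph_from_contact_table(t, "B", coords=coords))
        q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        moved = {n: x @ q.T + np.array([5., -2., 9.]) for n, x in coords.items()}
        _, s2 = com_distances(graph_from_contact_table(t, "B", coords=moved))
        assert s1["mean"] == pytest.approx(s2["mean"])
        assert s1["max"] == pytest.approx(s2["max"])

    def test_max_edge_matches_exhaustive_scan(self, kingdom_graphs):
        g = kingdom_graphs["E"]
        df, summary = com_distances(g)
        brute = max(
            float(np.linalg.norm(np.asarray(g.graph.nodes[u]["com"])
                                 - np.asarray(g.graph.nodes[v]["com"])))
            for u, v in g.graph.edges)
        assert summary["max"] == pytest.approx(brute)

    def test_missing_com_raises(self):
        t = table([("a", "G", "U", "b", "G", "U", "G_G")])
        g = graph_from_contact_table(t, "B", coords={"a": np.zeros(3)})
        with pytest.raises(ValueError, match="COM"):
            com_distances(g)


class TestFunctionalModules:
    def hand_graph(self):
        rows = [
            ("p1", "G", "U", "PTC", "site", "funct", "G_funct"),
            ("p2", "G", "U", "PTC", "site", "funct", "G_funct"),
            ("p2", "G", "U", "tunnel", "site", "funct", "G_funct"),
            ("p2", "G", "U", "tRNA_P", "site", "funct", "G_funct"),
            ("p3", "G", "U", "PTC", "site", "funct", "G_funct"),
            ("p3", "G", "U", "mRNA", "site", "funct", "G_funct"),
            ("p4", "G", "U", "p1", "G", "U", "G_G"),
            ("p5", "G", "U", "p5b", "G", "U", "G_G"),
        ]
        return graph_from_contact_table(
            table(rows), "E",
            subunits={"p1": "LSU", "p4": "SSU", "p5": "LSU", "p5b": "LSU"})

    def test_rule_application_matches_hand_labels(self):
        g = assign_functional_modules(self.hand_graph())
        modules = {n: d["functional_module"]
                   for n, d in g.graph.nodes(data=True)
                   if d["node_kind"] == "protein"}
        assert modules == {
            "p1": "PTC_module",       # touches one site category
            "p2": "bridge_3",         # PTC + tunnel + tRNA
            "p3": "bridge_2",         # PTC + mRNA
            "p4": "subunit_bridge",   # SSU protein bound to an LSU protein
            "p5": "none", "p5b": "none"}

    def test_trna_sites_are_one_category(self):
        rows = [("p1", "G", "U", "tRNA_A", "site", "funct", "G_funct"),
                ("p1", "G", "U", "tRNA_P", "site", "funct", "G_funct")]
        g = assign_functional_modules(graph_from_contact_table(table(rows), "E"))
        assert g.graph.nodes["p1"]["functional_module"] == "tRNA_module"

    def test_planted_bridge3_proteins_recovered(self, study, kingdom_graphs):
        for stage in ("B", "A", "E"):
            g = assign_functional_modules(kingdom_graphs[stage])
            found = sorted(n for n, d in g.graph.nodes(data=True)
                           if d.get("functional_module") == "bridge_3")
            assert found == study.truth["bridge3_proteins"][stage]


def test_graphml_export_roundtrips_topology(tmp_path, kingdom_graphs):
    import networkx as nx
    g = kingdom_graphs["B"]
    path = tmp_path / "b.graphml"
    to_graphml(g, path)
    back = nx.read_graphml(path)
    assert back.number_of_nodes() == g.graph.number_of_nodes()
    assert back.number_of_edges() == g.graph.number_of_edges()
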