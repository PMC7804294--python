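"""Network archaeology: core intersection and transition statistics."""

import numpy as np
import pandas as pd
import pytest

from riboarch.archaeology import (distance_trend, functional_contact_fraction,
                                  percent, transition_stats, universal_core)
from riboarch.network import canonical_status_pair, graph_from_contact_table

from test_network import table


def kgraph(rows, kingdom="B", coords=None):
    return graph_from_contact_table(table(rows), kingdom, coords=coords)


CORE_ROWS = [("uL1", "G", "U", "uL2", "G", "U", "G_G"),
             ("uL2", "G", "U", "uL3", "G", "U", "G_G"),
             ("uL3", "G", "U", "PTC", "site", "funct", "G_funct")]


class TestUniversalCore:
    def test_three_identical_graphs_yield_the_graph(self):
        graphs = {k: kgraph(CORE_ROWS, k) for k in ("A", "B", "E")}
        core = universal_core(graphs)
        assert core.n_edges == 3
        assert core.edge_pairs == graphs["A"].edge_pairs()
        assert core.n_contacts == 3

    def test_disjoint_graphs_yield_empty_core(self):
        graphs = {
            "A": kgraph([("a1", "G", "A", "a2", "G", "A", "G_G")], "A"),
            "B": kgraph([("b1", "G", "B", "b2", "G", "B", "G_G")], "B"),
            "E": kgraph([("e1", "G", "E", "e2", "G", "E", "G_G")], "E")}
        assert universal_core(graphs).n_edges == 0

    def test_missing_kingdom_raises(self):
        graphs = {k: kgraph(CORE_ROWS, k) for k in ("A", "B")}
        with pytest.raises(ValueError, match="E"):
            universal_core(graphs)

    def test_order_invariance(self, kingdom_graphs):
        g = {k: kingdom_graphs[k] for k in ("A", "B", "E")}
        h = {k: g[k] for k in ("E", "A", "B")}
        assert universal_core(g).edge_pairs == universal_core(h).edge_pairs

    def test_core_subset_of_every_kingdom(self, kingdom_graphs):
        core = universal_core(kingdom_graphs)
        for k in ("A", "B", "E"):
            assert core.edge_pairs <= kingdom_graphs[k].edge_pairs()

    def test_planted_core_size_recovered(self, study, kingdom_graphs):
        core = universal_core(kingdom_graphs)
        assert core.n_edges == study.truth["core_n_edges"] == 49
        # planted with multiplicity one, so both granularities agree
        assert core.n_contacts == 49


class TestTransitionStats:
    def test_child_equals_parent_gives_empty_stats(self):
        parent = kgraph(CORE_ROWS)
        child = kgraph(CORE_ROWS)
        ts = transition_stats(parent, child, "ABE_to_B")
        assert ts.n_new_contacts == 0 and ts.n_new_edges == 0
        assert ts.status_pair_fractions == {}
        assert ts.coevolved_pairs == []

    def test_reinforcement_counts_as_new_contact(self):
        parent = kgraph(CORE_ROWS)
        child = kgraph(CORE_ROWS + [
            ("uL1", "ext:C-mix", "Ub", "uL2", "G", "U", "ext_G")])
        ts = transition_stats(parent, child, "ABE_to_B")
        assert ts.n_new_contacts == 1
        assert ts.n_new_edges == 0       # the protein pair already existed
        assert ts.status_pair_fractions == {"Ub-U": 1.0}

    def test_planted_class_split_recovered_exactly(self):
        # 58/19/12/9/2 split over 100 planted protein-protein contacts
        rows = list(CORE_ROWS)
        plan = [("U-B", 58), ("B-B", 19), ("Ub-U", 12), ("Ub-B", 9),
                ("Ub-Ub", 2)]
        pools = {"U": [f"u{i}" for i in range(40)],
                 "B": [f"b{i}" for i in range(40)],
                 "Ub": [f"u{i}" for i in range(40, 80)]}
        k = 0
        for cls, count in plan:
            ta, tb = cls.split("-")
            for _ in range(count):
                pa, pb = f"{pools[ta][k % 40]}", f"{pools[tb][(k + 7) % 40]}x"
                comp_a = "ext:N-segment" if ta == "Ub" else "G"
                comp_b = "ext:C-helix" if tb == "Ub" else "G"
                ctype = ("ext_ext" if "ext" in comp_a and "ext" in comp_b
                         else "ext_G" if "ext" in comp_a or "ext" in comp_b
                         else "G_G")
                rows.append((f"{pa}_{k}", comp_a, ta, f"{pb}_{k}", comp_b, tb,
                             ctype))
                k += 1
        ts = transition_stats(kgraph(CORE_ROWS), kgraph(rows), "ABE_to_B")
        assert ts.n_new_contacts == 100
        assert ts.status_pair_fractions == {
            "U-B": 0.58, "B-B": 0.19, "Ub-U": 0.12, "Ub-B": 0.09,
            "Ub-Ub": 0.02}
        assert sum(ts.status_pair_fractions.values()) == pytest.approx(1.0)

    def test_coevolved_pairs_require_both_sides_acquired(self):
        rows = CORE_ROWS + [
            ("u1", "ext:N-mix", "Ub", "b1", "G", "B", "ext_G"),     # coevolved
            ("u2", "ext:N-mix", "Ub", "uL1", "G", "U", "ext_G"),    # one side old
            ("b2", "G", "B", "b3", "G", "B", "G_G")]                # coevolved
        ts = transition_stats(kgraph(CORE_ROWS), kgraph(rows), "ABE_to_B")
        assert ts.coevolved_pairs == [("b1", "u1"), ("b2", "b3")]

    def test_unknown_status_raises(self):
        rows = CORE_ROWS + [("x", "G", "Q", "y", "G", "B", "G_G")]
        with pytest.raises(ValueError, match="status"):
            transition_stats(kgraph(CORE_ROWS), kgraph(rows), "ABE_to_B")

    def test_fraction_maps_sum_to_one(self, study, kingdom_graphs):
        for name, parent, child in (("ABE_to_B", "ABE", "B"),
                                    ("ABE_to_A", "ABE", "A"),
                                    ("A_to_E", "A", "E")):
            ts = transition_stats(kingdom_graphs[parent],
                                  kingdom_graphs[child], name)
            assert sum(ts.status_pair_fractions.values()) == pytest.approx(
                1.0, abs=0.005)
            assert sum(ts.contact_type_fractions.values()) == pytest.approx(
                1.0, abs=0.005)


class TestFunctionalFraction:
    def test_no_functional_sites_gives_zero(self):
        g = kgraph([("a", "G", "U", "b", "G", "U", "G_G")])
        assert functional_contact_fraction(g) == 0.0

    def test_hand_counted_fraction(self):
        g = kgraph(CORE_ROWS)    # 1 of 3 contacts touches the PTC
        assert functional_contact_fraction(g) == pytest.approx(1 / 3)

    def test_new_only_requires_parent(self):
        g = kgraph(CORE_ROWS)
        with pytest.raises(ValueError):
            functional_contact_fraction(g, new_only=True)

    def test_planted_universal_fraction(self, study, kingdom_graphs):
        frac = functional_contact_fraction(kingdom_graphs["ABE"])
        assert frac == pytest.approx(study.truth["core_functional_fraction"])
        assert percent(frac) == 45


class TestDistanceTrend:
    def test_coincident_nodes_give_zero_means(self):
        coords = {n: np.zeros(3) for n in ("a", "b", "c", "PTC")}
        g = kgraph(CORE_ROWS[:2] + [("a", "G", "U", "b", "G", "U", "G_G")],
                   coords={**coords, "uL1": np.zeros(3), "uL2": np.zeros(3),
                           "uL3": np.zeros(3)})
        df = distance_trend([("ABE", g, None)])
        assert df["mean_distance"].iloc[0] == 0.0

    def test_single_stage_gives_single_value(self):
        g = kgraph([("a", "G", "U", "b", "G", "U", "G_G")],
                   coords={"a": np.zeros(3), "b": np.array([3., 0., 0.])})
        df = distance_trend([("only", g, None)])
        assert len(df) == 1 and df["mean_distance"].iloc[0] == pytest.approx(3.0)

    def test_stage_without_new_edges_is_flagged(self):
        g = kgraph([("a", "G", "U", "b", "G", "U", "G_G")],
                   coords={"a": np.zeros(3), "b": np.ones(3)})
        df = distance_trend([("ABE", g, None), ("B", g, g)])
        assert bool(df.loc[df["stage"] == "B", "undefined"].iloc[0])

    def test_planted_increasing_geometry_recovered(self, study, kingdom_graphs):
        df = distance_trend([
            ("ABE", kingdom_graphs["ABE"], None),
            ("B", kingdom_graphs["B"], kingdom_graphs["ABE"]),
            ("A", kingdom_graphs["A"], kingdom_graphs["ABE"]),
            ("E", kingdom_graphs["E"], kingdom_graphs["A"])])
        means = df.set_index("stage")["mean_distance"]
        for stage in ("ABE", "B", "A", "E"):
            assert means[stage] == pytest.approx(
                study.truth["stage_mean_distances"][stage])
        assert means.is_monotonic_increasing


@pytest.mark.parametrize("x,expected", [(0.449, 45), (0.465, 47),
                                        (0.345, 35), (0.02, 2), (0.0, 0)])
def test_percent_rounds_half_away_from_zero(x, expected):
    assert percent(x) == expected
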