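import numpy as np
import pytest
from conftest import make_library

from coretf.datasets import CORE_TF_PARTNERS, CORE_TFS, SELECTED_TFS, TARGET_ENRICHED_TFS
from coretf.io import InteractionTable
from coretf.network import (
    add_ppi_overlay,
    build_regulatory_network,
    rank_hubs,
    remove_node,
    to_networkx,
)


def interactions_from_partner_table():
    """Interaction pairs for the five core TFs from the published partner table."""
    pairs = []
    for tf, cols in CORE_TF_PARTNERS.items():
        for partner in cols["selected"] + cols["target_enriched"]:
            pairs.append((tf, partner))
    return InteractionTable.from_pairs(pairs, source="published")


class TestBuildRegulatoryNetwork:
    def test_membership_forces_single_edge(self):
        lib = make_library({"A E1": {"B", "C"}}, background_size=100, tf_names=True)
        net = build_regulatory_network(["A", "B"], lib)
        assert set(net.regulatory_edges) == {("A", "B")}

    def test_no_sets_gives_node_only_network(self):
        lib = make_library({"X E1": {"Y"}}, background_size=100, tf_names=True)
        net = build_regulatory_network(["A", "B"], lib)
        assert net.nodes == ("A", "B") and not net.regulatory_edges

    def test_parallel_experiments_collapse_with_count(self):
        lib = make_library(
            {"A E1": {"B"}, "A E2": {"B", "C"}, "A E3": {"Z"}},
            background_size=100, tf_names=True,
        )
        net = build_regulatory_network(["A", "B"], lib)
        assert net.regulatory_edges[("A", "B")] == ("A E1", "A E2")

    def test_self_loop_counted_once(self):
        lib = make_library({"A E1": {"A", "B"}}, background_size=100, tf_names=True)
        net = build_regulatory_network(["A", "B"], lib)
        assert ("A", "A") in net.regulatory_edges
        assert net.node_stats["A"]["regulatory_out_degree"] == 2

    def test_core_fixture_sox2_out_degree_maximal(self):
        """On a target library where SOX2's experiments contain the other
        four core TFs, SOX2 has the maximal regulatory out-degree."""
        lib = make_library(
            {
                "SOX2 E1": {"KLF4", "MITF", "G1"},
                "SOX2 E2": {"NR3C1", "NR3C2"},
                "KLF4 E1": {"SOX2", "G2"},
                "MITF E1": {"G3"},
            },
            background_size=22000, tf_names=True,
        )
        net = build_regulatory_network(CORE_TFS, lib)
        degrees = {t: net.node_stats[t]["regulatory_out_degree"] for t in net.nodes}
        assert max(degrees, key=degrees.get) == "SOX2"
        assert degrees["SOX2"] == 4


class TestPpiOverlay:
    def _base(self):
        lib = make_library({"A E1": {"B"}}, background_size=100, tf_names=True)
        return build_regulatory_network(["A", "B", "C"], lib)

    def test_empty_interactions_zero_counts(self):
        net = add_ppi_overlay(self._base(), InteractionTable(edges={}), {"ref": ["X"]})
        assert all(s["partner_total"] == 0 for s in net.node_stats.values())

    def test_partner_counts_are_distinct_symbols(self):
        table = InteractionTable.from_pairs([("A", "X"), ("A", "X"), ("A", "Y"), ("B", "Y")])
        net = add_ppi_overlay(self._base(), table, {"ref": ["X", "Y"]})
        assert net.node_stats["A"]["partners"]["ref"] == 2
        assert net.node_stats["B"]["partners"]["ref"] == 1

    def test_self_pair_counts_as_one_partner(self):
        table = InteractionTable.from_pairs([("A", "A")])
        net = add_ppi_overlay(self._base(), table, {"ref": ["A"]})
        assert net.node_stats["A"]["partners"]["ref"] == 1

    def test_edges_must_touch_a_node(self):
        table = InteractionTable.from_pairs([("X", "Y"), ("A", "X")])
        net = add_ppi_overlay(self._base(), table, {"ref": ["X", "Y"]})
        assert set(net.ppi_edges) == {("A", "X")}

    def test_idempotent_for_fixed_table(self):
        table = InteractionTable.from_pairs([("A", "B"), ("A", "C")])
        once = add_ppi_overlay(self._base(), table, {"ref": ["B", "C"]})
        twice = add_ppi_overlay(once, table, {"ref": ["B", "C"]})
        assert once.ppi_edges == twice.ppi_edges
        assert once.node_stats == twice.node_stats

    def test_stats_match_independent_recount(self):
        """node_stats agree with direct counting over random networks."""
        rng = np.random.default_rng(42)
        tfs = [f"T{i}" for i in range(8)]
        refs = {"r1": tfs[:5], "r2": tfs[3:]}
        sets = {
            f"{t} E1": {tfs[j] for j in rng.choice(8, 3, replace=False)}
            for t in tfs[:5]
        }
        lib = make_library(sets, background_size=100, tf_names=True)
        pairs = [
            (tfs[i], tfs[j])
            for i in range(8) for j in range(i, 8)
            if rng.random() < 0.4
        ]
        net = add_ppi_overlay(
            build_regulatory_network(tfs, lib),
            InteractionTable.from_pairs(pairs), refs,
        )
        for t in tfs:
            out = sum(1 for (u, _v) in net.regulatory_edges if u == t)
            assert net.node_stats[t]["regulatory_out_degree"] == out
            partners = net.partners(t)
            for rname, rmembers in refs.items():
                assert net.node_stats[t]["partners"][rname] == len(partners & set(rmembers))


class TestRankHubs:
    def test_single_node_scores_zero(self):
        lib = make_library({"Z E1": {"Q"}}, background_size=100, tf_names=True)
        net = build_regulatory_network(["A"], lib)
        ((tf, stats),) = rank_hubs(net)
        assert tf == "A" and stats["partner_total"] == 0

    def test_equal_counts_break_alphabetically(self):
        lib = make_library({"X E1": {"Q"}}, background_size=100, tf_names=True)
        net = build_regulatory_network(["B", "A"], lib)
        assert [t for t, _ in rank_hubs(net)] == ["A", "B"]

    def test_published_partner_table_puts_sox2_first(self):
        lib = make_library(
            {
                "SOX2 E1": {"KLF4", "MITF", "NR3C1", "NR3C2"},
                "KLF4 E1": {"SOX2"},
            },
            background_size=22000, tf_names=True,
        )
        net = build_regulatory_network(CORE_TFS, lib)
        net = add_ppi_overlay(
            net,
            interactions_from_partner_table(),
            {"selected": SELECTED_TFS, "target_enriched": TARGET_ENRICHED_TFS},
        )
        ranking = rank_hubs(net)
        assert ranking[0][0] == "SOX2"
        sox2 = net.node_stats["SOX2"]["partners"]
        for tf in CORE_TFS:
            if tf == "SOX2":
                continue
            other = net.node_stats[tf]["partners"]
            assert sox2["selected"] > other["selected"]
            assert sox2["target_enriched"] > other["target_enriched"]


class TestStructuralOps:
    def test_remove_node_removes_exactly_incident_edges(self):
        lib = make_library(
            {"A E1": {"B", "C"}, "B E1": {"C"}},
            background_size=100, tf_names=True,
        )
        net = add_ppi_overlay(
            build_regulatory_network(["A", "B", "C"], lib),
            InteractionTable.from_pairs([("A", "B"), ("B", "C")]),
            {"ref": ["A", "B", "C"]},
        )
        pruned = remove_node(net, "A")
        assert "A" not in pruned.nodes
        assert all("A" not in e for e in pruned.regulatory_edges)
        assert all("A" not in e for e in pruned.ppi_edges)
        # stats of a node not adjacent to A are unchanged
        assert pruned.node_stats["C"] == net.node_stats["C"]

    def test_networkx_export_keeps_both_edge_types(self):
        lib = make_library({"A E1": {"B"}}, background_size=100, tf_names=True)
        net = add_ppi_overlay(
            build_regulatory_network(["A", "B"], lib),
            InteractionTable.from_pairs([("A", "B")]),
            {"ref": ["A", "B"]},
        )
        g = to_networkx(net)
        types = {d["type"] for _, _, d in g.edges(data=True)}
        assert types == {"regulatory", "ppi"}
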