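import networkx as nx
import numpy as np
import pytest

from cernanet.datasets import CNAML_TOP_LNCRNA_PROFILE, profile_network
from cernanet.network import CompetingTriplet, build_network
from cernanet.topology import (
    count_pairs,
    extract_subnetwork,
    hub_class_counts,
    hub_nodes,
    node_degrees,
    rank_lncrnas,
    select_key_lncrnas,
)
from cernanet.types import ValidationError


def star_network(n_lnc):
    """One miRNA bridging n lncRNAs and one mRNA."""
    ts = [CompetingTriplet(f"L{i}", "M1", "G1", "lnc_up") for i in range(n_lnc)]
    up, _ = build_network(ts)
    return up


def random_network(rng, n_triplets=25):
    ts = {CompetingTriplet(f"L{rng.integers(6)}", f"M{rng.integers(5)}",
                           f"G{rng.integers(8)}", "lnc_up")
          for _ in range(n_triplets)}
    up, _ = build_network(sorted(ts))
    return up


class TestNodeDegrees:
    def test_single_triplet(self):
        up, _ = build_network([CompetingTriplet("L1", "M1", "G1", "lnc_up")])
        assert node_degrees(up) == {"L1": 1, "M1": 2, "G1": 1}

    def test_star(self):
        deg = node_degrees(star_network(6))
        assert deg["M1"] == 7  # 6 lncRNAs + 1 mRNA

    def test_agrees_with_adjacency_matrix_row_sums(self):
        net = random_network(np.random.default_rng(0))
        order = sorted(net.nodes)
        a = nx.to_numpy_array(net, nodelist=order)
        expected = dict(zip(order, a.sum(axis=1).astype(int)))
        assert node_degrees(net) == expected


class TestHubNodes:
    def test_strictly_exceeding_threshold(self):
        net = star_network(6)  # M1 degree 7
        hubs = hub_nodes(net, threshold=5)
        assert list(hubs["node"]) == ["M1"]
        assert hub_nodes(net, threshold=7).empty  # degree 7 is not > 7

    def test_degree_five_is_not_hub(self):
        net = star_network(4)  # M1 degree 5
        assert hub_nodes(net, threshold=5).empty

    def test_extreme_thresholds(self):
        net = random_network(np.random.default_rng(1))
        assert hub_nodes(net, threshold=net.number_of_edges()).empty
        assert len(hub_nodes(net, threshold=-1)) == net.number_of_nodes()

    def test_per_class_breakdown(self):
        hubs = hub_nodes(star_network(6), threshold=5)
        assert hub_class_counts(hubs) == {"miRNA": 1}


class TestCountPairs:
    def test_reproduces_profile_counts(self, ranking_network):
        for lnc, first, secondary in CNAML_TOP_LNCRNA_PROFILE:
            rec = count_pairs(ranking_network, lnc)
            assert (rec.first_pairs, rec.secondary_pairs) == (first, secondary)
            assert rec.total_pairs == first + secondary
            assert rec.node_degree == rec.first_pairs

    def test_secondary_counts_edges_not_paths(self):
        # G1 reachable via two miRNAs contributes two secondary pairs
        ts = [CompetingTriplet("L1", "M1", "G1", "lnc_up"),
              CompetingTriplet("L1", "M2", "G1", "lnc_up")]
        up, _ = build_network(ts)
        rec = count_pairs(up, "L1")
        assert (rec.first_pairs, rec.secondary_pairs) == (2, 2)

    def test_agrees_with_brute_force_on_random_networks(self):
        for seed in range(5):
            net = random_network(np.random.default_rng(seed))
            for lnc in [n for n, d in net.nodes(data=True)
                        if d["rna_class"] == "lncRNA"]:
                rec = count_pairs(net, lnc)
                mirnas = {n for n in net.neighbors(lnc)
                          if net.nodes[n]["rna_class"] == "miRNA"}
                brute_secondary = len({
                    (m, g) for m in mirnas for g in net.neighbors(m)
                    if net.nodes[g]["rna_class"] == "mRNA"})
                assert rec.first_pairs == len(mirnas)
                assert rec.secondary_pairs == brute_secondary

    def test_isolated_lncrna_all_zero(self):
        g = nx.Graph()
        g.add_node("L1", rna_class="lncRNA")
        rec = count_pairs(g, "L1")
        assert (rec.node_degree, rec.first_pairs, rec.secondary_pairs,
                rec.total_pairs) == (0, 0, 0, 0)

    def test_unknown_or_wrong_class_errors(self, ranking_network):
        with pytest.raises(ValidationError, match="unknown"):
            count_pairs(ranking_network, "nope")
        mirna = next(n for n, d in ranking_network.nodes(data=True)
                     if d["rna_class"] == "miRNA")
        with pytest.raises(ValidationError, match="not an lncRNA"):
            count_pairs(ranking_network, mirna)


class TestRanking:
    def test_profile_order_with_tie_break_on_total(self, ranking_network):
        ranked = rank_lncrnas(ranking_network)
        assert list(ranked["gene"][:3]) == ["XIST", "TUG1", "GABPB1-AS1"]
        assert list(ranked["number"]) == list(range(1, 11))
        # degree ties (TUG1 vs GABPB1-AS1, both 10) broken by total pairs
        assert ranked.loc[1, "total_pairs"] > ranked.loc[2, "total_pairs"]

    def test_total_is_first_plus_secondary_everywhere(self, ranking_network):
        ranked = rank_lncrnas(ranking_network)
        assert (ranked["total_pairs"] ==
                ranked["lnc_mirna_pairs"] + ranked["mi_mrna_pairs"]).all()

    def test_all_equal_degrees_lexicographic(self):
        ts = [CompetingTriplet(l, f"M:{l}", f"G:{l}", "lnc_up")
              for l in ["b", "a", "c"]]
        up, _ = build_network(ts)
        assert list(rank_lncrnas(up)["gene"]) == ["a", "b", "c"]

    def test_single_lncrna(self):
        up, _ = build_network([CompetingTriplet("L1", "M1", "G1", "lnc_up")])
        assert len(rank_lncrnas(up)) == 1


class TestKeySelection:
    def test_top3_intersection_on_profile(self, ranking_network):
        ranked = rank_lncrnas(ranking_network)
        assert set(select_key_lncrnas(ranked, k=3)) == {"XIST", "TUG1", "GABPB1-AS1"}

    def test_k_larger_than_list_returns_all(self, ranking_network):
        ranked = rank_lncrnas(ranking_network)
        assert len(select_key_lncrnas(ranked, k=100)) == len(ranked)

    def test_disjoint_top_k_returns_empty(self):
        # L_deg has the degree lead, L_tot the total-pairs lead
        ts = [CompetingTriplet("L_deg", f"M{i}", "G0", "lnc_up") for i in range(3)]
        ts += [CompetingTriplet("L_tot", "MX", f"G{i}", "lnc_up") for i in range(9)]
        up, _ = build_network(ts)
        ranked = rank_lncrnas(up)
        assert select_key_lncrnas(ranked, k=1) == []


class TestSubnetwork:
    def test_xist_shaped_subnetwork_node_count(self, ranking_network):
        sub = extract_subnetwork(ranking_network, "XIST")
        rec = count_pairs(ranking_network, "XIST")
        mrnas = {n for n, d in sub.nodes(data=True) if d["rna_class"] == "mRNA"}
        assert sub.number_of_nodes() == 1 + rec.first_pairs + len(mrnas)
        # in this expansion every secondary edge has its own mRNA
        assert len(mrnas) == rec.secondary_pairs

    def test_subgraph_and_idempotent(self, ranking_network):
        sub = extract_subnetwork(ranking_network, "TUG1")
        assert set(sub.nodes) <= set(ranking_network.nodes)
        assert set(sub.edges) <= {tuple(e) for e in ranking_network.edges} | \
            {tuple(reversed(e)) for e in ranking_network.edges}
        sub2 = extract_subnetwork(sub, "TUG1")
        assert set(sub2.nodes) == set(sub.nodes)
        assert set(map(frozenset, sub2.edges)) == set(map(frozenset, sub.edges))

    def test_isolated_lncrna_singleton(self):
        g = nx.Graph()
        g.add_node("L1", rna_class="lncRNA")
        sub = extract_subnetwork(g, "L1")
        assert set(sub.nodes) == {"L1"}

    def test_pair_counts_preserved_in_subnetwork(self, ranking_network):
        for lnc, first, secondary in CNAML_TOP_LNCRNA_PROFILE[:3]:
            sub = extract_subnetwork(ranking_network, lnc)
            rec = count_pairs(sub, lnc)
            assert (rec.first_pairs, rec.secondary_pairs) == (first, secondary)
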