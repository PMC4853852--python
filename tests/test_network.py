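"""Topology scores against brute-force oracles; network assembly rules."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from krnet.network import (
    build_global_network,
    extract_cgmc,
    identify_kr_hubs,
    kr_subnetworks,
    neighborhood_connectivity,
    stress_centrality,
    topology_scores,
)

from conftest import make_signature


def brute_force_stress(G: nx.Graph) -> dict:
    """Enumerate every shortest path of every pair; count interior visits."""
    stress = {v: 0 for v in G}
    for s, t in itertools.combinations(G.nodes, 2):
        if not nx.has_path(G, s, t):
            continue
        for path in nx.all_shortest_paths(G, s, t):
            for v in path[1:-1]:
                stress[v] += 1
    return stress


class TestStressCentrality:
    def test_path_graph(self):
        G = nx.path_graph(["a", "b", "c"])
        s = stress_centrality(G)
        assert s == {"a": 0, "b": 1, "c": 0}

    def test_complete_graph_all_zero(self):
        s = stress_centrality(nx.complete_graph(4))
        assert all(v == 0 for v in s.values())

    def test_star_center(self):
        G = nx.star_graph(4)  # center 0, four leaves
        s = stress_centrality(G)
        assert s[0] == brute_force_stress(G)[0] == 6

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for i in range(50):
            n = int(rng.integers(4, 13))
            G = nx.gnp_random_graph(n, float(rng.uniform(0.2, 0.7)), seed=int(rng.integers(2**31)))
            assert stress_centrality(G) == brute_force_stress(G)

    def test_relabeling_preserves_score_multiset(self):
        G = nx.gnp_random_graph(10, 0.4, seed=7)
        H = nx.relabel_nodes(G, {i: f"n{(i * 3) % 10}" for i in range(10)})
        assert sorted(stress_centrality(G).values()) == sorted(stress_centrality(H).values())

    def test_disconnected_components_independent(self):
        G = nx.union(nx.path_graph(3), nx.path_graph(3), rename=("a", "b"))
        s = stress_centrality(G)
        assert s["a1"] == 1 and s["b1"] == 1

    def test_empty_graph(self):
        assert stress_centrality(nx.Graph()) == {}


class TestNeighborhoodConnectivity:
    def test_star(self):
        nc = neighborhood_connectivity(nx.star_graph(4))
        assert nc[0] == pytest.approx(1.0)
        assert nc[1] == pytest.approx(4.0)

    def test_regular_graph(self):
        G = nx.cycle_graph(6)  # 2-regular
        assert all(v == pytest.approx(2.0) for v in neighborhood_connectivity(G).values())

    def test_isolated_node_zero(self):
        G = nx.Graph()
        G.add_node("x")
        assert neighborhood_connectivity(G)["x"] == 0.0

    def test_matches_networkx_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            G = nx.gnp_random_graph(int(rng.integers(4, 13)), 0.5,
                                    seed=int(rng.integers(2**31)))
            G.remove_nodes_from(list(nx.isolates(G)))
            if not G:
                continue
            ours = neighborhood_connectivity(G)
            ref = nx.average_neighbor_degree(G)
            for v in G:
                assert ours[v] == pytest.approx(ref[v])


class TestBuildGlobalNetwork:
    def _sigs(self):
        gs = make_signature({"G1": "up", "G2": "down", "G3": "up"}, other_features=["G4"])
        ms = make_signature({"M1": "up"}, layer="mirna")
        return gs, ms

    def test_edge_with_nonsignificant_endpoint_dropped(self):
        gs, ms = self._sigs()
        G = build_global_network(
            gs, ms, [("G1", "G2"), ("G1", "G4")],
            pd.DataFrame(columns=["mirna", "gene", "r"]),
        )
        assert set(G.edges()) == {("G1", "G2")}
        assert "G4" not in G

    def test_duplicates_and_self_loops_collapsed(self):
        gs, ms = self._sigs()
        G = build_global_network(
            gs, ms, [("G1", "G2"), ("G2", "G1"), ("G1", "G1")],
            pd.DataFrame(columns=["mirna", "gene", "r"]),
        )
        assert G.number_of_edges() == 1

    def test_functional_mirna_edges_typed(self):
        gs, ms = self._sigs()
        G = build_global_network(
            gs, ms, [("G1", "G2")],
            pd.DataFrame({"mirna": ["M1"], "gene": ["G3"], "r": [0.9]}),
        )
        assert G.nodes["M1"]["type"] == "mirna"
        assert G.edges["M1", "G3"]["source"] == "mirna_functional"

    def test_no_retained_edges_rejected(self):
        gs, ms = self._sigs()
        with pytest.raises(ValueError, match="no retained edges"):
            build_global_network(gs, ms, [("G4", "G4")],
                                 pd.DataFrame(columns=["mirna", "gene", "r"]))

    def test_node_set_equals_incident_significant_features(self, default_bundle,
                                                           default_signatures):
        from krnet.integration import (functional_interactions, load_target_table,
                                       mirna_regulated_genes)
        bundle, sigs = default_bundle, default_signatures
        targets = load_target_table(bundle["targets"])
        mr, active = mirna_regulated_genes(sigs["gene"], sigs["mirna"], targets)
        cand = [(m, g) for m, g in targets[["mirna", "gene"]].itertuples(index=False, name=None)
                if m in active and g in mr]
        fe = functional_interactions(cand, bundle["matched"])
        G = build_global_network(sigs["gene"], sigs["mirna"], bundle["interactome"], fe)
        # independent recount of the expected node set
        sg = sigs["gene"].significant_features
        expected = set()
        for u, v in bundle["interactome"].edges():
            if u in sg and v in sg and u != v:
                expected |= {u, v}
        sm = sigs["mirna"].significant_features
        for _, row in fe.iterrows():
            if row["mirna"] in sm and row["gene"] in sg:
                expected |= {row["mirna"], row["gene"]}
        assert set(G.nodes) == expected


class TestExtractCgmc:
    def test_star_extraction(self):
        G = nx.Graph([("gmc", "a"), ("gmc", "b"), ("b", "far_b"), ("x", "y")])
        sub = extract_cgmc(G, {"gmc"})
        assert set(sub.nodes) == {"gmc", "a", "b"}
        assert set(map(frozenset, sub.edges())) == {frozenset({"gmc", "a"}), frozenset({"gmc", "b"})}

    def test_induced_edges_between_neighbors_kept(self):
        G = nx.Graph([("gmc", "a"), ("gmc", "b"), ("a", "b")])
        sub = extract_cgmc(G, {"gmc"})
        assert sub.has_edge("a", "b")

    def test_isolated_gmc_retained(self):
        G = nx.Graph([("x", "y")])
        G.add_node("gmc")
        sub = extract_cgmc(G, {"gmc"})
        assert set(sub.nodes) == {"gmc"}

    def test_absent_gmcs_rejected(self):
        with pytest.raises(ValueError, match="no GMC"):
            extract_cgmc(nx.path_graph(3), {"missing"})


class TestKrHubs:
    def test_double_top_rank_always_kr(self):
        G = nx.star_graph(12)
        scores = topology_scores(G)
        krs = identify_kr_hubs(scores, cutoff=10)
        assert 0 in krs  # center tops stress

    def test_tied_stress_gets_average_rank(self):
        G = nx.Graph([("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")])  # path
        scores = topology_scores(G)
        # b and d are symmetric: identical stress and nc -> identical ranks
        assert scores.loc["b", "rank_stress"] == scores.loc["d", "rank_stress"]
        assert scores.loc["b", "ar_score"] == scores.loc["d", "ar_score"]

    def test_ar_invariant_to_monotone_transform(self):
        G = nx.gnp_random_graph(15, 0.3, seed=3)
        scores = topology_scores(G)
        from scipy.stats import rankdata
        s = scores["stress"].to_numpy(dtype=float)
        transformed = rankdata(-np.exp(s / (s.max() + 1)), method="average")
        np.testing.assert_allclose(transformed, scores["rank_stress"])

    def test_small_network_everyone_kr_with_warning(self, caplog):
        G = nx.path_graph(4)
        scores = topology_scores(G)
        krs = identify_kr_hubs(scores, cutoff=10)
        assert len(krs) == 4

    def test_empty_scores_rejected(self):
        with pytest.raises(ValueError):
            identify_kr_hubs(pd.DataFrame())

    def test_planted_hubs_called(self, default_bundle, default_signatures):
        from krnet.integration import (functional_interactions, gmc_set,
                                       load_target_table, methylation_regulated_genes,
                                       mirna_regulated_genes)
        bundle, sigs = default_bundle, default_signatures
        truth = bundle["truth"]
        targets = load_target_table(bundle["targets"])
        mr, active = mirna_regulated_genes(sigs["gene"], sigs["mirna"], targets)
        meth_g, ann = methylation_regulated_genes(sigs["gene"], sigs["methylation"],
                                                  truth.site_to_gene)
        cand = [(m, g) for m, g in targets[["mirna", "gene"]].itertuples(index=False, name=None)
                if m in active and g in mr]
        fe = functional_interactions(cand, bundle["matched"])
        gm = gmc_set(mr, meth_g, fe)
        G = build_global_network(sigs["gene"], sigs["mirna"], bundle["interactome"], fe)
        cgmc = extract_cgmc(G, gm.gmcs)
        krs = identify_kr_hubs(topology_scores(cgmc), cutoff=10)
        assert truth.hubs <= set(krs)


class TestKrSubnetworks:
    def test_first_neighbor_subgraph(self):
        G = nx.Graph([("kr", "x"), ("kr", "y"), ("x", "y"), ("y", "z")])
        subs = kr_subnetworks(G, ["kr"])
        assert set(subs["kr"].nodes) == {"kr", "x", "y"}
        assert subs["kr"].has_edge("x", "y")

    def test_isolated_kr_singleton(self):
        G = nx.Graph()
        G.add_node("kr")
        subs = kr_subnetworks(G, ["kr"])
        assert set(subs["kr"].nodes) == {"kr"}

    def test_neighbor_counts_match_adjacency_recount(self):
        G = nx.gnp_random_graph(20, 0.3, seed=5)
        krs = [0, 1, 2]
        subs = kr_subnetworks(G, krs)
        for k in krs:
            assert subs[k].number_of_nodes() - 1 == len(list(G.neighbors(k)))
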