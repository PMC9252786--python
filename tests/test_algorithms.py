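import networkx as nx
import numpy as np
import pytest

import oracles
from drugnet import (
    DrugnetError,
    betweenness_among_seeds,
    degree_to_seeds,
    drug_gene_graph,
    gene_graph,
    harmonic_to_seeds,
    keypathwayminer_greedy,
    multi_steiner,
    network_proximity,
    run_algorithm,
    trustrank,
)
from conftest import pick_seeds, random_gene_graph


class TestTrustRank:
    def test_single_node_fixed_point(self):
        G = nx.Graph()
        G.add_node("A")
        sm = trustrank(G, {"A"}, damping=0.7)
        assert sm.scores["A"] == pytest.approx(1.0)

    def test_path_matches_dense_power_iteration(self, path_graph):
        sm = trustrank(path_graph, {"A"}, damping=0.85, tolerance=1e-14, max_iter=100000)
        oracle = oracles.dense_rwr(path_graph, {"A"}, 0.85)
        for v in path_graph.nodes:
            assert sm.scores[v] == pytest.approx(oracle[v], abs=1e-12)
        assert sm.scores["B"] > sm.scores["C"]

    def test_all_seeds_on_cycle_gives_equal_scores(self):
        G = nx.cycle_graph(6)
        G = nx.relabel_nodes(G, {i: f"n{i}" for i in G.nodes})
        sm = trustrank(G, set(G.nodes))
        vals = list(sm.scores.values())
        assert all(v == pytest.approx(vals[0]) for v in vals)

    def test_requires_seeds_and_valid_damping(self, path_graph):
        with pytest.raises(DrugnetError):
            trustrank(path_graph, set())
        with pytest.raises(DrugnetError):
            trustrank(path_graph, {"A"}, damping=1.0)

    def test_gene_scores_unaffected_by_drug_layer(self, small_interactome):
        """Sink contract: drugs receive mass but never shift gene scores."""
        seeds = {"A", "B"}
        gene_only = trustrank(gene_graph(small_interactome), seeds)
        layered = trustrank(drug_gene_graph(small_interactome), seeds)
        for g in small_interactome.genes:
            assert layered.scores[g] == pytest.approx(gene_only.scores[g], abs=1e-12)
        for d in ("dX", "dY", "dZ"):
            assert layered.scores[d] > 0

    def test_drug_targeting_seeds_outscores_peripheral_drug(self, small_interactome):
        sm = trustrank(drug_gene_graph(small_interactome), {"A", "B"})
        assert sm.scores["dX"] > sm.scores["dY"]


class TestDegreeToSeeds:
    def test_hub_adjacent_to_three_seed_leaves(self):
        G = nx.star_graph(3)
        G = nx.relabel_nodes(G, {0: "hub", 1: "s1", 2: "s2", 3: "s3"})
        sm = degree_to_seeds(G, {"s1", "s2", "s3"})
        assert sm.scores["hub"] == 3.0

    def test_node_without_seed_neighbor_scores_zero(self, path_graph):
        assert degree_to_seeds(path_graph, {"A"}).scores["C"] == 0.0

    def test_drug_scores_count_seed_targets(self, small_interactome):
        sm = degree_to_seeds(drug_gene_graph(small_interactome), {"A", "B"})
        assert sm.scores["dX"] == 2.0
        assert sm.scores["dY"] == 0.0


class TestHarmonicToSeeds:
    def test_closed_form_on_path(self, path_graph):
        sm = harmonic_to_seeds(path_graph, {"A"})
        assert sm.scores["B"] == pytest.approx(1.0)
        assert sm.scores["C"] == pytest.approx(0.5)

    def test_disconnected_node_scores_zero(self, path_graph):
        path_graph.add_node("Z")
        assert harmonic_to_seeds(path_graph, {"A"}).scores["Z"] == 0.0

    def test_drug_distance_runs_through_targets(self, small_interactome):
        sm = harmonic_to_seeds(drug_gene_graph(small_interactome), {"A"})
        # dY -> D -> C -> B -> A: distance 4
        assert sm.scores["dY"] == pytest.approx(1 / 4)


class TestBetweenness:
    def test_single_path_midpoint(self, path_graph):
        sm = betweenness_among_seeds(path_graph, {"A", "C"})
        assert sm.scores["B"] == pytest.approx(1.0)
        assert sm.scores["A"] == sm.scores["C"] == 0.0

    def test_parallel_routes_split_evenly(self):
        G = nx.Graph()
        G.add_edges_from([("s", "m1"), ("m1", "t"), ("s", "m2"), ("m2", "t")])
        sm = betweenness_among_seeds(G, {"s", "t"})
        assert sm.scores["m1"] == pytest.approx(0.5)
        assert sm.scores["m2"] == pytest.approx(0.5)

    def test_needs_at_least_two_seeds(self, path_graph):
        with pytest.raises(DrugnetError, match=">= 2"):
            betweenness_among_seeds(path_graph, {"A"})

    def test_drugs_never_scored_on_gene_paths(self, small_interactome):
        sm = betweenness_among_seeds(drug_gene_graph(small_interactome), {"A", "D"})
        assert all(d not in sm.scores for d in ("dX", "dY", "dZ"))
        assert sm.scores["B"] > 0 and sm.scores["C"] > 0


class TestMultiSteiner:
    def test_adjacent_seed_pair(self, path_graph):
        sub = multi_steiner(path_graph, {"A", "B"})
        assert sub.nodes == {"A", "B"}
        assert sub.edges == {("A", "B")}
        assert sub.cost == pytest.approx(1.0)

    def test_single_seed_is_node_only(self, path_graph):
        sub = multi_steiner(path_graph, {"B"})
        assert sub.nodes == {"B"} and sub.edges == set()

    def test_trees_are_connected_acyclic_and_span_terminals(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            G = random_gene_graph(rng, n_max=15, connected=True)
            seeds = pick_seeds(G, rng, 2, 5)
            sub = multi_steiner(G, seeds, num_trees=4, rng_seed=1)
            assert seeds <= sub.nodes
            for tree in sub.trees:
                T = nx.Graph(list(tree.edges))
                T.add_nodes_from(tree.nodes)
                assert nx.is_tree(T)
                assert seeds <= set(T.nodes)

    def test_seeds_across_components_warn_and_use_largest(self, caplog):
        G = nx.Graph()
        G.add_edges_from([("a", "b"), ("b", "c"), ("x", "y")])
        with caplog.at_level("WARNING", logger="drugnet"):
            sub = multi_steiner(G, {"a", "c", "x"})
        assert sub.nodes == {"a", "b", "c"}
        assert any("component" in r.message for r in caplog.records)

    def test_deterministic_for_fixed_rng_seed(self):
        rng = np.random.default_rng(9)
        G = random_gene_graph(rng, n_max=20, connected=True)
        seeds = pick_seeds(G, rng, 3, 6)
        a = multi_steiner(G, seeds, rng_seed=42)
        b = multi_steiner(G, seeds, rng_seed=42)
        assert a.nodes == b.nodes and a.edges == b.edges and a.cost == b.cost


class TestKeyPathwayMiner:
    def test_connected_seed_set_with_zero_budget(self):
        G = nx.path_graph(4)
        G = nx.relabel_nodes(G, {0: "s1", 1: "s2", 2: "s3", 3: "x"})
        sub = keypathwayminer_greedy(G, {"s1", "s2", "s3"}, k=0)
        assert sub.nodes == {"s1", "s2", "s3"}

    def test_forced_bridge_topology(self):
        G = nx.Graph()
        G.add_edges_from([("s1", "x"), ("x", "s2")])
        assert keypathwayminer_greedy(G, {"s1", "s2"}, k=1).nodes == {"s1", "x", "s2"}
        sub0 = keypathwayminer_greedy(G, {"s1", "s2"}, k=0)
        assert sub0.nodes == {"s1"}  # deterministic tie-break: smallest node set

    def test_k0_disconnected_seeds_largest_component(self):
        G = nx.Graph()
        G.add_edges_from([("s1", "s2"), ("s2", "s3"), ("s4", "s5")])
        sub = keypathwayminer_greedy(G, {"s1", "s2", "s3", "s4", "s5"}, k=0)
        assert sub.nodes == {"s1", "s2", "s3"}

    def test_output_always_connected_within_budget(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            G = random_gene_graph(rng, n_max=14)
            seeds = pick_seeds(G, rng, 2, 5)
            for k in (0, 1, 2):
                sub = keypathwayminer_greedy(G, seeds, k=k)
                assert nx.is_connected(G.subgraph(sub.nodes))
                assert len(sub.nodes - seeds) <= k


class TestNetworkProximity:
    def test_targets_inside_seed_set_give_zero_distance(self, small_interactome):
        G = gene_graph(small_interactome)
        res = network_proximity(G, {"A", "B"}, small_interactome,
                                n_permutations=20, rng_seed=0, min_bin_size=2)
        raw = {r.drug_id: r.raw_distance for r in res.records}
        assert raw["dX"] == pytest.approx(0.0)  # dX targets {A, B} = seeds

    def test_path_distance(self, small_interactome):
        G = gene_graph(small_interactome)
        res = network_proximity(G, {"A"}, small_interactome,
                                n_permutations=20, rng_seed=0, min_bin_size=2)
        raw = {r.drug_id: r.raw_distance for r in res.records}
        assert raw["dY"] == pytest.approx(3.0)  # D -> C -> B -> A

    def test_unreachable_targets_reported_unranked(self, small_interactome):
        from drugnet import DrugGeneInteraction, Interactome
        inter = Interactome(
            genes=list(small_interactome.genes.values()),
            drugs=list(small_interactome.drugs.values()),
            ggi=small_interactome.ggi,
            dgi=list(small_interactome.dgi) + [DrugGeneInteraction("dZ", "F", "inhibitor")],
        )
        G = gene_graph(inter)
        res = network_proximity(G, {"A"}, inter, n_permutations=20,
                                rng_seed=0, min_bin_size=2)
        # dF targets only the isolated gene F
        inter2 = Interactome(
            genes=list(small_interactome.genes.values()),
            drugs=list(small_interactome.drugs.values()),
            ggi=small_interactome.ggi,
            dgi=[DrugGeneInteraction("dY", "F", "inhibitor")],
        )
        res2 = network_proximity(gene_graph(inter2), {"A"}, inter2,
                                 n_permutations=20, rng_seed=0, min_bin_size=2)
        assert ("dY", "no target in the seed component") in res2.unranked

    def test_minimum_permutations_enforced(self, small_interactome):
        G = gene_graph(small_interactome)
        with pytest.raises(DrugnetError, match="n_permutations"):
            network_proximity(G, {"A"}, small_interactome, n_permutations=5)

    def test_deterministic_for_fixed_rng_seed(self, small_interactome):
        G = gene_graph(small_interactome)
        kw = dict(n_permutations=25, rng_seed=123, min_bin_size=2)
        a = network_proximity(G, {"A", "B"}, small_interactome, **kw)
        b = network_proximity(G, {"A", "B"}, small_interactome, **kw)
        assert [(r.drug_id, r.z_score) for r in a.records] == \
               [(r.drug_id, r.z_score) for r in b.records]


class TestDispatch:
    def test_run_algorithm_by_name(self, path_graph):
        assert run_algorithm("degree", path_graph, {"A"}).algorithm == "degree"
        with pytest.raises(DrugnetError, match="unknown algorithm"):
            run_algorithm("pagerankplus", path_graph, {"A"})
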